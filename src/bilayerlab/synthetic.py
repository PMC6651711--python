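"""Synthetic membrane fixtures with machine-readable ground truth.

Every generator here emulates one class of observable the pipeline estimates
from MD trajectories — alkyl chains with tunable orientational order and
gauche statistics, Helfrich-spectrum height fields, area fluctuation series,
and Ornstein–Uhlenbeck constraint-force records — so each downstream
estimator has a parameter-recovery test that needs no simulation data.

All randomness flows through one ``numpy.random.Generator`` per call,
seeded from the spec; identical spec + seed gives bitwise-identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .constants import KB_J, kBT_kJ_mol
from .datatypes import (AreaSeries, ChainTopology, FrameEnsemble, ForceWindow,
                        ParameterError)

# geometry of the synthetic alkyl chains (nm, degrees)
_CC_BOND = 0.153
_CH_BOND = 0.109
_CCC_ANGLE = 111.0
_TRANS = 180.0
_GAUCHE = 60.0


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class SyntheticChainSpec:
    """Alkyl-chain fixture: target |SCD| plateau and gauche probability."""

    n_chains: int = 64
    n_carbons: int = 16
    order_param_target: float = 0.45
    gauche_prob: float = 0.10
    seed: int = 0
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.n_carbons < 4:
            raise ParameterError("n_carbons must be >= 4")
        if not 0.0 <= self.gauche_prob <= 1.0:
            raise ParameterError("gauche_prob must lie in [0, 1]")
        if not 0.0 <= self.order_param_target <= 1.0:
            raise ParameterError("order_param_target must lie in [0, 1]")


@dataclass
class SyntheticSurfaceSpec:
    """Height-field fixture drawn from a Helfrich q^-4 / q^-2 spectrum."""

    Lx: float = 20.0
    Ly: float = 20.0
    n_grid: int = 16
    KC_true: float = 20.0        # kBT
    chi_true: float = 0.0        # kBT/nm^2
    temperature: float = 298.0
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.KC_true <= 0:
            raise ParameterError("KC_true must be positive")
        if self.chi_true < 0:
            raise ParameterError("chi_true must be >= 0")
        if self.n_grid < 8:
            raise ParameterError("n_grid must be >= 8")


@dataclass
class SyntheticForceSpec:
    """Constraint-force fixture: mean-force profile + OU fluctuations.

    ``mean_force_profile`` maps z (nm) to the mean force on the permeant
    (kJ/mol/nm).  The ground-truth local diffusivity is
    D = (RT)^2 / (sigma^2 * tau) and the ground-truth free energy is the
    integral of the mean force from bulk inward.
    """

    z_values: Sequence[float] = field(default_factory=lambda: tuple(np.round(np.arange(0.0, 2.81, 0.2), 10)))
    mean_force_profile: Union[Callable[[np.ndarray], np.ndarray], None] = None
    force_variance: float = 400.0     # (kJ/mol/nm)^2
    correlation_time: float = 0.5     # ps
    dt: float = 0.05                  # ps
    n_steps: int = 10000              # per replicate (500 ps at default dt)
    temperature: float = 298.0
    seed: int = 0
    n_replicates: int = 10

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        if z.size < 2 or np.any(np.diff(z) <= 0):
            raise ParameterError("z_values must be strictly increasing")
        if self.correlation_time <= 0:
            raise ParameterError("correlation_time must be positive")
        if self.dt >= self.correlation_time:
            raise ParameterError(
                "dt must resolve the correlation time (dt < correlation_time)")
        if self.force_variance < 0:
            raise ParameterError("force_variance must be >= 0")


# --------------------------------------------------------------------------
# axial (Watson-type) orientation sampling
# --------------------------------------------------------------------------

def _mean_p2(kappa: float, n_nodes: int = 4001) -> float:
    """<P2(c)> under p(c) ∝ exp(kappa c^2) on c in [-1, 1]."""
    c = np.linspace(-1.0, 1.0, n_nodes)
    w = np.exp(kappa * (c ** 2 - (1.0 if kappa > 0 else 0.0)))  # overflow guard
    z = np.trapezoid(w, c)
    c2 = np.trapezoid(c ** 2 * w, c) / z
    return 0.5 * (3.0 * c2 - 1.0)


def watson_kappa_for_order(order: float) -> float:
    """Concentration kappa of the axial distribution with <P2> = order."""
    if not 0.0 <= order < 1.0:
        raise ParameterError("order must lie in [0, 1) for finite kappa")
    if order == 0.0:
        return 0.0
    return brentq(lambda k: _mean_p2(k) - order, 0.0, 2.0e4, xtol=1e-10)


def sample_axial_vectors(order: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit vectors whose polar cosine follows the Watson-type axial law.

    Returns an (n, 3) array with analytically known <P2(cos theta)> = order.
    ``order == 1`` returns exact +z alignment.
    """
    if order == 1.0:
        v = np.zeros((n, 3))
        v[:, 2] = 1.0
        return v
    kappa = watson_kappa_for_order(order)
    grid = np.linspace(-1.0, 1.0, 8193)
    pdf = np.exp(kappa * (grid ** 2 - (1.0 if kappa > 0 else 0.0)))
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(grid))])
    cdf /= cdf[-1]
    c = np.interp(rng.random(n), cdf, grid)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(np.clip(1.0 - c ** 2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), c])


# --------------------------------------------------------------------------
# chain fixture
# --------------------------------------------------------------------------

def _nerf_extend(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom d given a-b-c and internal coordinates (NeRF construction)."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(theta),
                        bond * math.sin(theta) * math.cos(phi),
                        bond * math.sin(theta) * math.sin(phi)])
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def _build_backbone(n_carbons: int, dihedrals_deg: np.ndarray) -> np.ndarray:
    pos = np.zeros((n_carbons, 3))
    theta = math.radians(_CCC_ANGLE)
    pos[1] = pos[0] + np.array([0.0, 0.0, _CC_BOND])
    # third atom at the tetrahedral-like C-C-C angle from the first bond
    pos[2] = pos[1] + _CC_BOND * np.array([0.0, math.sin(math.pi - theta),
                                           math.cos(math.pi - theta)])
    for i in range(3, n_carbons):
        pos[i] = _nerf_extend(pos[i - 3], pos[i - 2], pos[i - 1],
                              _CC_BOND, _CCC_ANGLE, dihedrals_deg[i - 3])
    return pos


def _align_to_axis(pos: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Rigid rotation taking the chain end-to-end vector onto ``axis``."""
    v = pos[-1] - pos[0]
    v = v / np.linalg.norm(v)
    axis = axis / np.linalg.norm(axis)
    cross = np.cross(v, axis)
    s = np.linalg.norm(cross)
    cdot = float(np.dot(v, axis))
    if s < 1e-12:
        if cdot > 0:
            return pos - pos[0]
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(v[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        k = np.cross(v, perp)
        k /= np.linalg.norm(k)
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + 2.0 * K @ K
        return (pos - pos[0]) @ R.T
    k = cross / s
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + K * s + K @ K * (1.0 - cdot)
    return (pos - pos[0]) @ R.T


def generate_chain_frames(spec: SyntheticChainSpec):
    """Build a lattice of alkyl chains with known order and gauche statistics.

    Returns ``(FrameEnsemble, ChainTopology)``.  Each carbon carries two
    explicit hydrogens whose bond directions are drawn from an axial
    distribution with <P2(cos theta)> equal to ``order_param_target``; the
    backbone dihedral sequence is Bernoulli(``gauche_prob``) gauche/trans.
    Ground truth is attached in ``FrameEnsemble.metadata["ground_truth"]``.
    """
    rng = np.random.default_rng(spec.seed)
    nc, npc = spec.n_chains, spec.n_carbons
    n_dih = npc - 3
    side = int(math.ceil(math.sqrt(nc)))
    spacing = 0.6
    box_xy = side * spacing + spacing
    box_z = 6.0
    z_center = box_z / 2.0

    atoms_per_chain = npc * 3  # carbons + 2 H each
    n_atoms = nc * atoms_per_chain
    coords = np.zeros((spec.n_frames, n_atoms, 3))
    chains, ch_bonds, leaflets, head_atoms, species = [], [], [], [], []
    gauche_draws = np.zeros((spec.n_frames, nc, n_dih), dtype=bool)

    for f in range(spec.n_frames):
        for ci in range(nc):
            base = ci * atoms_per_chain
            is_upper = ci < nc // 2
            gx, gy = ci % side, (ci // side) % side
            origin = np.array([spacing / 2 + gx * spacing,
                               spacing / 2 + gy * spacing,
                               z_center + (1.0 if is_upper else -1.0)])
            gauche = rng.random(n_dih) < spec.gauche_prob
            signs = np.where(rng.random(n_dih) < 0.5, 1.0, -1.0)
            dihedrals_deg = np.where(gauche, signs * _GAUCHE, _TRANS)
            backbone = _build_backbone(npc, dihedrals_deg)
            axis = np.array([0.0, 0.0, -1.0 if is_upper else 1.0])
            backbone = _align_to_axis(backbone, axis) + origin
            ch_dirs = sample_axial_vectors(spec.order_param_target, 2 * npc, rng)
            coords[f, base:base + npc] = backbone
            h_pos = backbone.repeat(2, axis=0) + _CH_BOND * ch_dirs
            coords[f, base + npc:base + atoms_per_chain] = h_pos
            gauche_draws[f, ci] = gauche
            if f == 0:
                carbon_idx = list(range(base, base + npc))
                chains.append(carbon_idx)
                for k in range(npc):
                    ch_bonds.append((base + k, base + npc + 2 * k))
                    ch_bonds.append((base + k, base + npc + 2 * k + 1))
                leaflets.append("upper" if is_upper else "lower")
                head_atoms.append(base)
                species.append("synthetic")

    box = np.tile([box_xy, box_xy, box_z], (spec.n_frames, 1))
    ens = FrameEnsemble(
        coordinates=coords, box=box, time=np.arange(spec.n_frames, dtype=float),
        metadata={"ground_truth": {
            "order_param_target": spec.order_param_target,
            "gauche_prob": spec.gauche_prob,
            "realized_gauche_fraction": float(gauche_draws.mean()),
            "n_dihedral_samples": int(gauche_draws.size),
        }})
    topo = ChainTopology(chains=chains, ch_bonds=ch_bonds,
                         dihedrals=ChainTopology.dihedrals_from_chains(chains),
                         leaflet=leaflets, headgroup_atoms=head_atoms,
                         species=species)
    return ens, topo


# --------------------------------------------------------------------------
# height-field fixture
# --------------------------------------------------------------------------

@dataclass
class SurfaceEnsemble:
    """Gridded height fields h(x, y) per frame, with generation ground truth."""

    heights: np.ndarray  # (n_frames, n, n), nm
    Lx: float
    Ly: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.heights.shape[0]


def _mode_power(qsq: np.ndarray, KC: float, chi: float, area: float) -> np.ndarray:
    """Per-mode <|h_q|^2> (nm^2) for the Helfrich + tilt spectrum, kBT units.

    Convention: h_q = FFT2(h)/N^2, so <|h_q|^2> = kBT / (A (KC q^4 + chi q^2)).
    """
    with np.errstate(divide="ignore"):
        s = 1.0 / (area * (KC * qsq ** 2 + chi * qsq))
    s[qsq == 0] = 0.0
    return s


def generate_height_frames(spec: SyntheticSurfaceSpec) -> SurfaceEnsemble:
    """Sample membrane height fields from the bending + tilt spectrum.

    Each allowed wavevector receives an independent Gaussian amplitude with
    <|h_q|^2> = kBT / (A (KC_true q^4 + chi_true q^2)); the zero mode is
    removed.  Surfaces are returned on an n_grid x n_grid mesh.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_grid
    qx = 2.0 * np.pi * np.fft.fftfreq(n, d=spec.Lx / n)
    qy = 2.0 * np.pi * np.fft.fftfreq(n, d=spec.Ly / n)
    qsq = qx[:, None] ** 2 + qy[None, :] ** 2
    area = spec.Lx * spec.Ly
    target = _mode_power(qsq, spec.KC_true, spec.chi_true, area)
    amp = n * np.sqrt(target)  # scales FFT2(white)/N^2 to the target power

    heights = np.empty((spec.n_frames, n, n))
    for f in range(spec.n_frames):
        g = rng.standard_normal((n, n))
        hq = np.fft.fft2(g) / n ** 2 * amp
        heights[f] = np.real(np.fft.ifft2(hq) * n ** 2)
    return SurfaceEnsemble(
        heights=heights, Lx=spec.Lx, Ly=spec.Ly,
        metadata={"ground_truth": {"KC_true": spec.KC_true,
                                   "chi_true": spec.chi_true,
                                   "temperature": spec.temperature}})


# --------------------------------------------------------------------------
# area-fluctuation fixture
# --------------------------------------------------------------------------

def generate_area_series(mean_area_per_mol: float, KA_true: float, N: int,
                         temperature: float, n_frames: int, seed: int) -> AreaSeries:
    """Gaussian per-molecule-area series whose fluctuations encode KA_true.

    ``KA_true`` in mN/m; the variance is kBT <A> / (N KA_true) so the
    fluctuation estimator recovers KA_true.
    """
    if KA_true <= 0:
        raise ParameterError("KA_true must be positive")
    rng = np.random.default_rng(seed)
    ka_si = KA_true * 1e-3  # N/m
    var_nm4 = KB_J * temperature * mean_area_per_mol * 1e18 / (N * ka_si)
    samples = rng.normal(mean_area_per_mol, math.sqrt(var_nm4), n_frames)
    samples = np.clip(samples, 1e-6, None)
    return AreaSeries(area_per_molecule=samples, n_molecules=N,
                      metadata={"ground_truth": {"KA_true": KA_true,
                                                 "temperature": temperature}})


# --------------------------------------------------------------------------
# tilt-angle fixture
# --------------------------------------------------------------------------

def generate_tilt_angles(chi_true: float, alpha0: float, n: int, seed: int,
                         alpha_max: float = np.pi / 2) -> np.ndarray:
    """Inverse-sample tilt angles from P(alpha) ∝ sin(alpha) exp(-chi/2 (alpha-alpha0)^2).

    ``chi_true`` in kBT/rad^2; chi_true = 0 gives the uniform-on-the-
    hemisphere sin(alpha) law.
    """
    if chi_true < 0:
        raise ParameterError("chi_true must be >= 0")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, alpha_max, 16385)
    pdf = np.sin(grid) * np.exp(-0.5 * chi_true * (grid - alpha0) ** 2)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


# --------------------------------------------------------------------------
# constraint-force fixture
# --------------------------------------------------------------------------

def gaussian_barrier(height: float, center: float, width: float):
    """Mean-force and free-energy callables for a Gaussian barrier.

    G(z) = height * exp(-(z-center)^2 / (2 width^2)); the mean force on the
    permeant is f(z) = -dG/dz.
    """
    def dg(z):
        z = np.asarray(z, dtype=float)
        return height * np.exp(-(z - center) ** 2 / (2.0 * width ** 2))

    def force(z):
        z = np.asarray(z, dtype=float)
        return height * (z - center) / width ** 2 * np.exp(
            -(z - center) ** 2 / (2.0 * width ** 2))

    return force, dg


def _ou_series(n: int, sigma2: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary OU path via the exact discrete-time update."""
    from scipy.signal import lfilter

    sigma = math.sqrt(sigma2)
    u = np.empty(n)
    u[0] = rng.normal(0.0, sigma)
    u[1:] = rng.normal(0.0, sigma * math.sqrt(1.0 - rho ** 2), n - 1)
    # x[i] = rho x[i-1] + u[i]  with x[0] = u[0] drawn from the stationary law
    return lfilter([1.0], [1.0, -rho], u)


def generate_force_windows(spec: SyntheticForceSpec) -> list:
    """Constraint-force windows: mean-force profile + stationary OU noise.

    Ground truth (per-window D and the analytic free-energy profile
    referenced to the outermost z) rides along in each window's metadata.
    """
    rng = np.random.default_rng(spec.seed)
    z_values = np.asarray(spec.z_values, dtype=float)
    profile = spec.mean_force_profile or (lambda z: np.zeros_like(np.asarray(z, float)))
    rho = math.exp(-spec.dt / spec.correlation_time)
    rt = kBT_kJ_mol(spec.temperature)
    d_true = np.inf if spec.force_variance == 0 else \
        rt ** 2 / (spec.force_variance * spec.correlation_time)

    # reference free energy by dense quadrature of the mean-force profile
    z_fine = np.linspace(z_values[0], z_values[-1], 20001)
    f_fine = np.asarray(profile(z_fine), dtype=float)
    cum = np.concatenate([[0.0], np.cumsum((f_fine[1:] + f_fine[:-1]) * 0.5 * np.diff(z_fine))])
    dg_fine = cum[-1] - cum  # integral from z to z_max
    dg_true = np.interp(z_values, z_fine, dg_fine)

    windows = []
    for iz, z in enumerate(z_values):
        fz = float(np.asarray(profile(z), dtype=float))
        for rep in range(spec.n_replicates):
            noise = (_ou_series(spec.n_steps, spec.force_variance, rho, rng)
                     if spec.force_variance > 0 else np.zeros(spec.n_steps))
            windows.append(ForceWindow(
                z=float(z), forces=fz + noise, dt=spec.dt,
                temperature=spec.temperature, replicate=rep,
                metadata={"ground_truth": {
                    "mean_force": fz,
                    "dG_true": float(dg_true[iz]),
                    "D_true_nm2_ps": d_true,
                    "sigma2": spec.force_variance,
                    "tau": spec.correlation_time,
                }}))
    return windows
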