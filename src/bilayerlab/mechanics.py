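"""Fluctuation-based mechanical moduli and Helfrich bending energetics.

Three moduli are estimated from equilibrium fluctuations:

* area compressibility ``KA = kBT <A_mol> / (N var(A_mol))`` (mN/m),
* molecular tilt modulus ``chi`` from the quadratic well of the
  Boltzmann-inverted, sin(alpha)-corrected tilt-angle distribution
  (kBT/rad^2),
* bending modulus ``KC`` from a weighted fit of the height-fluctuation
  power spectrum ``<|h_q|^2> = kBT / (A (KC q^4 + chi_s q^2))`` (kBT).

The bending energy of a fitted surface is the Helfrich small-deformation
form (KC/2) integral (c1+c2)^2 dA with c1+c2 = del^2 h by default.
"""
from __future__ import annotations

import logging
import math
import warnings
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit

from .constants import kBT_J, kBT_kJ_mol
from .datatypes import (AreaSeries, ChainTopology, EstimatorError,
                        FluctuationSpectrum, FrameEnsemble, HeightField,
                        BendingEnergyProfile, ParameterError, TiltDistribution)
from .synthetic import SurfaceEnsemble

logger = logging.getLogger(__name__)

#: default spectrum fit cutoff: exclude protrusion-dominated modes above
#: q = 2 pi / (1.5 nm)
DEFAULT_Q_CUT = 2.0 * np.pi / 1.5


# --------------------------------------------------------------------------
# area compressibility
# --------------------------------------------------------------------------

def area_compressibility(areas: AreaSeries, temperature: float,
                         n_blocks: int = 5):
    """KA in mN/m from per-molecule area fluctuations.

    Returns ``(KA, KA_se)``.  A zero-variance (rigid) series returns
    ``(inf, nan)``; series shorter than 100 frames trigger a warning.
    """
    a = areas.area_per_molecule
    n = a.size
    if n < 100:
        warnings.warn("fewer than 100 frames: KA estimate is unreliable",
                      stacklevel=2)
    var = float(np.var(a, ddof=1)) if n > 1 else 0.0
    if var == 0.0:
        return float("inf"), float("nan")

    def _ka(series):
        v = np.var(series, ddof=1)
        if v == 0:
            return np.inf
        # kBT [J] * <A>[nm^2] / (N * var[nm^4]) -> N/m needs 1e18; -> mN/m 1e21
        return kBT_J(temperature) * np.mean(series) / (areas.n_molecules * v) * 1e21

    ka = _ka(a)
    nb = min(n_blocks, n // 2) or 1
    blocks = np.array_split(a, nb)
    block_kas = np.array([_ka(b) for b in blocks])
    se = float(np.std(block_kas, ddof=1) / math.sqrt(nb)) if nb > 1 else float("nan")
    return float(ka), se


# --------------------------------------------------------------------------
# molecular tilt modulus
# --------------------------------------------------------------------------

def chain_tilt_angles(frames: FrameEnsemble, topo: ChainTopology) -> np.ndarray:
    """Tilt angle of each chain in each frame, folded to [0, pi/2].

    The chain direction is the vector from the first to the second-last
    carbon; upper- and lower-leaflet chains point opposite ways along z, so
    the angle to the bilayer normal uses |v_z|.
    """
    angles = []
    for f in range(frames.n_frames):
        pos = frames.coordinates[f]
        for chain in topo.chains:
            v = pos[chain[-2]] - pos[chain[0]]
            angles.append(math.acos(min(1.0, abs(v[2]) / np.linalg.norm(v))))
    return np.asarray(angles)


def tilt_modulus_from_angles(alpha: np.ndarray, n_bins: int = 72,
                             fit_depth_kBT: float = 2.0):
    """chi (kBT/rad^2) by Boltzmann inversion of the tilt-angle histogram.

    F(alpha) = -ln[P(alpha)/sin(alpha)] in kBT; a quadratic is fitted over
    the window where F <= F(alpha0) + ``fit_depth_kBT``.  Returns
    ``(chi, chi_se, TiltDistribution)``.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.size < 100:
        raise EstimatorError("too few tilt samples")
    if np.ptp(alpha) < 1e-6:
        raise EstimatorError("degenerate tilt distribution (zero width)")
    counts, edges = np.histogram(alpha, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    p = counts / (counts.sum() * width)
    good = counts > 0
    if (~good).any():
        logger.info("%d empty tilt bins dropped", int((~good).sum()))
    f_kbt = np.full(n_bins, np.nan)
    f_kbt[good] = -np.log(p[good] / np.sin(centers[good]))
    i0 = int(np.nanargmin(f_kbt))
    fmin = f_kbt[i0]
    window = good & (f_kbt <= fmin + fit_depth_kBT)
    if window.sum() < 5:
        raise EstimatorError("fewer than 5 usable points in the fit window")
    x = centers[window]
    y = f_kbt[window]
    # weights: delta F = delta P / P = 1/sqrt(count)
    w = 1.0 / np.sqrt(counts[window])
    coeffs, cov = np.polyfit(x, y, 2, w=1.0 / w, cov=True)
    chi = 2.0 * coeffs[0]
    chi_se = 2.0 * math.sqrt(max(cov[0, 0], 0.0))
    alpha0 = float(-coeffs[1] / (2.0 * coeffs[0])) if coeffs[0] != 0 else float(x[np.argmin(y)])
    dist = TiltDistribution(alpha=centers, counts=counts, p_alpha=p,
                            free_energy=f_kbt, alpha0=alpha0)
    return float(chi), chi_se, dist


def tilt_modulus(frames: FrameEnsemble, topo: ChainTopology, **kwargs):
    """Tilt modulus straight from a trajectory (see tilt_modulus_from_angles)."""
    return tilt_modulus_from_angles(chain_tilt_angles(frames, topo), **kwargs)


# --------------------------------------------------------------------------
# truncated-Fourier height field
# --------------------------------------------------------------------------

def _basis_matrix(x, y, Lx, Ly, basis):
    cols, labels = [], []
    for m in range(3):
        for n in range(3):
            if basis == "combined":
                arg = 2 * np.pi * (m * x / Lx + n * y / Ly)
                sin_col, cos_col = np.sin(arg), np.cos(arg)
            else:
                sin_col = np.sin(2 * np.pi * m * x / Lx) * np.sin(2 * np.pi * n * y / Ly)
                cos_col = np.cos(2 * np.pi * m * x / Lx) * np.cos(2 * np.pi * n * y / Ly)
            cols.append(sin_col)
            labels.append(("a", m, n))
            cols.append(cos_col)
            labels.append(("b", m, n))
    return np.column_stack(cols), labels


def fit_height_field(points: np.ndarray, Lx: float, Ly: float,
                     basis: str = "combined") -> HeightField:
    """Least-squares truncated-Fourier surface through headgroup positions.

    ``points`` is (n, 3): x, y, h.  Requires at least 18 points (the basis
    size); raises on a rank-deficient design (e.g. collinear points).
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 18:
        raise ParameterError("need >= 18 points to fit the 18-function basis")
    A, labels = _basis_matrix(points[:, 0], points[:, 1], Lx, Ly, basis)
    # the all-zero sine column (m = n = 0) never contributes
    usable = ~np.all(np.abs(A) < 1e-14, axis=0)
    if np.linalg.matrix_rank(A[:, usable]) < usable.sum():
        raise EstimatorError("rank-deficient design: points are degenerate")
    coef = np.zeros(A.shape[1])
    sol, *_ = np.linalg.lstsq(A[:, usable], points[:, 2], rcond=None)
    coef[usable] = sol
    resid = points[:, 2] - A @ coef
    a = np.zeros((3, 3))
    b = np.zeros((3, 3))
    for c, (kind, m, n) in zip(coef, labels):
        (a if kind == "a" else b)[m, n] = c
    return HeightField(a=a, b=b, Lx=Lx, Ly=Ly,
                       residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                       basis=basis)


# --------------------------------------------------------------------------
# fluctuation spectrum and KC
# --------------------------------------------------------------------------

def height_spectrum(surfaces: Union[SurfaceEnsemble, np.ndarray],
                    Lx: Optional[float] = None,
                    Ly: Optional[float] = None) -> FluctuationSpectrum:
    """Mode-averaged power spectrum <|h_q|^2> of gridded height fields.

    Fourier amplitudes use the convention h_q = FFT2(h)/N^2; modes of equal
    |q| are pooled into shells.  With a single frame the per-mode variance is
    undefined and the spectrum is flagged unreliable (infinite se).
    """
    if isinstance(surfaces, SurfaceEnsemble):
        h = surfaces.heights
        Lx, Ly = surfaces.Lx, surfaces.Ly
    else:
        h = np.asarray(surfaces, dtype=float)
        if Lx is None or Ly is None:
            raise ParameterError("Lx and Ly required for raw arrays")
    if h.ndim == 2:
        h = h[None]
    n_frames, n, m = h.shape
    qx = 2.0 * np.pi * np.fft.fftfreq(n, d=Lx / n)
    qy = 2.0 * np.pi * np.fft.fftfreq(m, d=Ly / m)
    qmag = np.sqrt(qx[:, None] ** 2 + qy[None, :] ** 2)
    power = np.abs(np.fft.fft2(h, axes=(1, 2)) / (n * m)) ** 2  # (frames, n, m)

    qflat = np.round(qmag.ravel(), 9)
    shells = np.unique(qflat)
    shells = shells[shells > 0]
    q_out, p_out, se_out = [], [], []
    pflat = power.reshape(n_frames, -1)
    for q in shells:
        sel = qflat == q
        per_frame = pflat[:, sel].mean(axis=1)
        q_out.append(q)
        p_out.append(per_frame.mean())
        if n_frames > 1:
            se_out.append(per_frame.std(ddof=1) / math.sqrt(n_frames))
        else:
            se_out.append(np.inf)
    return FluctuationSpectrum(q=np.array(q_out), power=np.array(p_out),
                               se=np.array(se_out), n_frames=n_frames,
                               area=Lx * Ly, unreliable=n_frames == 1)


def fit_spectrum_moduli(spectrum: FluctuationSpectrum, temperature: float,
                        q_cut: float = DEFAULT_Q_CUT):
    """Weighted fit of kBT/(A (KC q^4 + chi_s q^2)) below ``q_cut``.

    Energies are in kBT units, so KC comes out in kBT and chi_s in kBT/nm^2.
    Returns ``(KC, KC_se, chi_s, chi_s_se, diagnostics)``.
    """
    mask = (spectrum.q > 0) & (spectrum.q <= q_cut) & (spectrum.power > 0)
    if mask.sum() < 3:
        raise EstimatorError("fewer than 3 usable q shells below the cutoff")
    q = spectrum.q[mask]
    p = spectrum.power[mask]
    se = spectrum.se[mask]
    if not np.all(np.isfinite(se)):
        raise EstimatorError("spectrum has no ensemble averaging (n_frames = 1)")
    area = spectrum.area

    def model(qv, kc, chi):
        return 1.0 / (area * (kc * qv ** 4 + chi * qv ** 2))

    kc0 = 1.0 / (area * p[0] * q[0] ** 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(model, q, p, p0=(max(kc0, 1e-3), 0.1),
                               sigma=se, absolute_sigma=True,
                               bounds=([1e-12, 0.0], [np.inf, np.inf]),
                               maxfev=20000)
    kc, chi = popt
    kc_se, chi_se = np.sqrt(np.diag(pcov))
    pred = model(q, *popt)
    ss_res = np.sum((p - pred) ** 2)
    ss_tot = np.sum((p - p.mean()) ** 2)
    diagnostics = {
        "q_cut": q_cut, "n_shells": int(mask.sum()),
        "r_squared": float(1.0 - ss_res / ss_tot) if ss_tot > 0 else float("nan"),
        "KC_joule": float(kc * kBT_J(temperature)),
    }
    return float(kc), float(kc_se), float(chi), float(chi_se), diagnostics


def bending_modulus_spectrum(frames: Union[FrameEnsemble, SurfaceEnsemble],
                             topo: Optional[ChainTopology] = None,
                             temperature: float = 298.0,
                             n_grid: int = 16, q_cut: float = DEFAULT_Q_CUT):
    """KC (kBT) and spectral chi (kBT/nm^2) from height fluctuations.

    Accepts either gridded surfaces (e.g. from the synthetic generator) or a
    trajectory plus topology, in which case the bilayer mid-surface is the
    mean of per-leaflet truncated-Fourier fits to headgroup positions,
    evaluated on an ``n_grid`` mesh per frame.
    """
    if isinstance(frames, SurfaceEnsemble):
        spec = height_spectrum(frames)
    else:
        if topo is None:
            raise ParameterError("topology required for trajectory input")
        surfaces, Lx, Ly = midsurface_grids(frames, topo, n_grid)
        spec = height_spectrum(surfaces, Lx, Ly)
    if np.allclose(spec.power, 0.0):
        raise EstimatorError("all height modes are zero: spectrum unfittable")
    kc, kc_se, chi, chi_se, diag = fit_spectrum_moduli(spec, temperature, q_cut)
    return kc, kc_se, chi, chi_se, spec, diag


def midsurface_grids(frames: FrameEnsemble, topo: ChainTopology, n_grid: int):
    """Per-frame mid-surface height grids: mean of upper/lower leaflet fits."""
    Lx = float(frames.box[0, 0])
    Ly = float(frames.box[0, 1])
    xs = (np.arange(n_grid) + 0.5) * Lx / n_grid
    ys = (np.arange(n_grid) + 0.5) * Ly / n_grid
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    head = np.asarray(topo.headgroup_atoms)
    upper = np.asarray([lf == "upper" for lf in topo.leaflet])
    grids = np.empty((frames.n_frames, n_grid, n_grid))
    for f in range(frames.n_frames):
        pos = frames.coordinates[f]
        fields = []
        for sel in (head[upper], head[~upper]):
            pts = pos[sel]
            hf = fit_height_field(pts, Lx, Ly)
            fields.append(hf.evaluate(X, Y))
        mid = 0.5 * (fields[0] + fields[1])
        grids[f] = mid - mid.mean()
    return grids, Lx, Ly


# --------------------------------------------------------------------------
# Helfrich bending energy
# --------------------------------------------------------------------------

def bending_energy(height: HeightField, KC: float, temperature: float = 298.0,
                   n_quad: int = 32, curvature: str = "small_slope") -> float:
    """Helfrich bending energy (kJ/mol) of a fitted surface.

    E = (KC/2) integral (c1 + c2)^2 dA over the periodic cell, by
    Gauss-Legendre quadrature on an ``n_quad`` x ``n_quad`` grid.  ``KC`` is
    in kBT; the result is converted with kBT at ``temperature``.  The
    small-slope form c1 + c2 = del^2 h is the default; ``curvature="monge"``
    uses the full Monge-gauge mean curvature.  A refinement changing the
    result by more than 1% raises a warning carrying both values.
    """
    if KC <= 0:
        raise ParameterError("KC must be positive")

    def total_curv_sq(n):
        nodes, weights = np.polynomial.legendre.leggauss(n)
        x = 0.5 * (nodes + 1.0) * height.Lx
        y = 0.5 * (nodes + 1.0) * height.Ly
        wx = weights * height.Lx / 2.0
        wy = weights * height.Ly / 2.0
        X, Y = np.meshgrid(x, y, indexing="ij")
        if curvature == "small_slope":
            c = height.laplacian(X, Y)
        else:
            c = _monge_mean_curvature(height, X, Y)
        return float(np.einsum("i,j,ij->", wx, wy, c ** 2))

    integral = total_curv_sq(n_quad)
    refined = total_curv_sq(2 * n_quad)
    if integral != 0 and abs(refined - integral) / max(abs(refined), 1e-300) > 0.01:
        warnings.warn(f"quadrature not converged: {integral:.6g} vs refined "
                      f"{refined:.6g}; reporting the refined value", stacklevel=2)
        integral = refined
    return 0.5 * KC * kBT_kJ_mol(temperature) * integral


def _monge_mean_curvature(height: HeightField, X, Y, eps: float = 1e-5):
    """2H = ((1+hy^2)hxx - 2 hx hy hxy + (1+hx^2)hyy) / (1+hx^2+hy^2)^{3/2}."""
    h = height.evaluate
    hx = (h(X + eps, Y) - h(X - eps, Y)) / (2 * eps)
    hy = (h(X, Y + eps) - h(X, Y - eps)) / (2 * eps)
    hxx = (h(X + eps, Y) - 2 * h(X, Y) + h(X - eps, Y)) / eps ** 2
    hyy = (h(X, Y + eps) - 2 * h(X, Y) + h(X, Y - eps)) / eps ** 2
    hxy = (h(X + eps, Y + eps) - h(X + eps, Y - eps)
           - h(X - eps, Y + eps) + h(X - eps, Y - eps)) / (4 * eps ** 2)
    num = (1 + hy ** 2) * hxx - 2 * hx * hy * hxy + (1 + hx ** 2) * hyy
    return num / (1 + hx ** 2 + hy ** 2) ** 1.5


def bending_profile(fields_by_z: dict, KC: float, temperature: float = 298.0,
                    min_frames: int = 10) -> BendingEnergyProfile:
    """Mean bending energy vs permeant depth, flat reference subtracted.

    ``fields_by_z`` maps each constraint depth z (nm) to a list of fitted
    HeightField surfaces from that window.  A flat surface has zero bending
    energy, so the reference subtraction is implicit in the quadratic form.
    Windows with fewer than ``min_frames`` surfaces are flagged.
    """
    zs = np.array(sorted(fields_by_z))
    means, ses, curv, flagged = [], [], [], []
    for z in zs:
        fields = fields_by_z[z]
        if len(fields) < min_frames:
            flagged.append(float(z))
        energies = np.array([bending_energy(hf, KC, temperature) for hf in fields])
        means.append(energies.mean())
        ses.append(energies.std(ddof=1) / math.sqrt(len(energies))
                   if len(energies) > 1 else float("nan"))
        rms = [np.sqrt(np.mean(hf.laplacian(
            *np.meshgrid(np.linspace(0, hf.Lx, 16, endpoint=False),
                         np.linspace(0, hf.Ly, 16, endpoint=False),
                         indexing="ij")) ** 2)) for hf in fields]
        curv.append(float(np.mean(rms)))
    return BendingEnergyProfile(z=zs, delta_e_bend=np.array(means),
                                se=np.array(ses),
                                mean_total_curvature=np.array(curv),
                                flagged=flagged)
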