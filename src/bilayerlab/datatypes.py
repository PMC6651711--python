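"""In-memory data model shared across the analysis pipeline.

All containers carry values in the internal unit system (nm, ps, kJ/mol);
see :mod:`bilayerlab.constants`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import yaml


class BilayerlabError(Exception):
    """Base class for package errors."""


class ParseError(BilayerlabError):
    """Malformed input file."""


class ParameterError(BilayerlabError):
    """Invalid or unreachable parameter value."""


class EstimatorError(BilayerlabError):
    """An estimator cannot produce a meaningful result from its input."""


# --------------------------------------------------------------------------
# trajectory / topology substrate
# --------------------------------------------------------------------------

@dataclass
class FrameEnsemble:
    """Per-frame particle coordinates with orthorhombic box dimensions.

    Parameters
    ----------
    coordinates : (n_frames, n_atoms, 3) array, nm
    box : (n_frames, 3) array, nm — (Lx, Ly, Lz) per frame
    time : (n_frames,) array, ps
    metadata : free-form dict (atom names, ground-truth tags, ...)
    """

    coordinates: np.ndarray
    box: np.ndarray
    time: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ParameterError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.box.shape != (self.coordinates.shape[0], 3):
            raise ParameterError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ParameterError("box dimensions must be positive")
        if self.time.shape != (self.coordinates.shape[0],):
            raise ParameterError("time must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ChainTopology:
    """Mapping from atom indices to alkyl chains and bonded features.

    ``chains`` lists carbon backbones head-to-tail.  ``ch_bonds`` is either a
    list of (carbon, hydrogen) atom-index pairs or the string ``"reconstruct"``
    to request ideal-geometry hydrogen placement on united-atom carbons.
    """

    chains: list
    ch_bonds: Union[list, str]
    dihedrals: list
    leaflet: list
    headgroup_atoms: list
    species: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for chain in self.chains:
            if len(chain) < 4:
                raise ParameterError("every chain needs >= 4 carbons")
        for quad in self.dihedrals:
            if len(quad) != 4:
                raise ParameterError("dihedrals must be 4-atom tuples")
        if not self.species:
            self.species = ["chain"] * len(self.chains)
        if len(self.leaflet) != len(self.chains):
            raise ParameterError("one leaflet label per chain required")

    @staticmethod
    def dihedrals_from_chains(chains: Sequence[Sequence[int]]) -> list:
        quads = []
        for chain in chains:
            for i in range(len(chain) - 3):
                quads.append(tuple(chain[i:i + 4]))
        return quads

    def to_yaml(self, path) -> None:
        payload = {
            "chains": [list(map(int, c)) for c in self.chains],
            "ch_bonds": (self.ch_bonds if isinstance(self.ch_bonds, str)
                         else [[int(c), int(h)] for c, h in self.ch_bonds]),
            "dihedrals": [list(map(int, q)) for q in self.dihedrals],
            "leaflet": list(self.leaflet),
            "headgroup_atoms": list(map(int, self.headgroup_atoms)),
            "species": list(self.species),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "ChainTopology":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        ch_bonds = payload["ch_bonds"]
        if not isinstance(ch_bonds, str):
            ch_bonds = [tuple(pair) for pair in ch_bonds]
        return cls(
            chains=payload["chains"],
            ch_bonds=ch_bonds,
            dihedrals=[tuple(q) for q in payload["dihedrals"]],
            leaflet=payload["leaflet"],
            headgroup_atoms=payload["headgroup_atoms"],
            species=payload.get("species", []),
        )


@dataclass
class AreaSeries:
    """Per-frame lateral area per molecule (nm^2) for N molecules/leaflet."""

    area_per_molecule: np.ndarray
    n_molecules: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.area_per_molecule = np.asarray(self.area_per_molecule, dtype=float)
        if np.any(self.area_per_molecule <= 0):
            raise ParameterError("areas must be positive")
        if self.n_molecules <= 0:
            raise ParameterError("n_molecules must be positive")


@dataclass
class ForceWindow:
    """Constraint-force time series on a permeant held at depth z.

    Forces in kJ/mol/nm along the bilayer normal, sampled every ``dt`` ps.
    """

    z: float
    forces: np.ndarray
    dt: float
    temperature: float
    replicate: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.size < 2:
            raise ParameterError("force series needs >= 2 samples")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")

    @property
    def mean_force(self) -> float:
        return float(np.mean(self.forces))


# --------------------------------------------------------------------------
# analysis results
# --------------------------------------------------------------------------

@dataclass
class ZProfile:
    """Generic z-binned profile: value(z) with a standard error."""

    z: np.ndarray
    value: np.ndarray
    se: np.ndarray
    label: str = ""
    units: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.se = np.asarray(self.se, dtype=float)


@dataclass
class OrderParameterProfile:
    """|SCD| per carbon index, with the signed average retained."""

    species: str
    carbon_index: np.ndarray
    scd_abs: np.ndarray
    scd_signed: np.ndarray
    se: np.ndarray


@dataclass
class GaucheProfile:
    species: str
    dihedral_index: np.ndarray
    fraction: np.ndarray
    se: np.ndarray
    n_excluded: int = 0


@dataclass
class CavityProfile:
    z: np.ndarray
    pcav: np.ndarray
    gridsize: float
    metadata: dict = field(default_factory=dict)


@dataclass
class PhaseCall:
    verdict: str  # "S", "Ld", or "conflicting"
    evidence: dict


@dataclass
class TiltDistribution:
    alpha: np.ndarray          # bin centers, rad
    counts: np.ndarray
    p_alpha: np.ndarray        # normalized density over alpha
    free_energy: np.ndarray    # kBT units
    alpha0: float


@dataclass
class HeightField:
    """Truncated-Fourier membrane surface h(x, y).

    ``a`` and ``b`` are 3x3 coefficient arrays (modes m, n in 0..2) for the
    sine and cosine terms; ``basis`` selects the combined-argument form
    sin/cos(2pi(m x/Lx + n y/Ly)) or the separable product form.
    """

    a: np.ndarray
    b: np.ndarray
    Lx: float
    Ly: float
    residual_rms: float = 0.0
    basis: str = "combined"

    def evaluate(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        h = np.zeros(np.broadcast(x, y).shape)
        for m in range(3):
            for n in range(3):
                if self.basis == "combined":
                    arg = 2 * np.pi * (m * x / self.Lx + n * y / self.Ly)
                    h = h + self.a[m, n] * np.sin(arg) + self.b[m, n] * np.cos(arg)
                else:
                    sx, cx = np.sin(2 * np.pi * m * x / self.Lx), np.cos(2 * np.pi * m * x / self.Lx)
                    sy, cy = np.sin(2 * np.pi * n * y / self.Ly), np.cos(2 * np.pi * n * y / self.Ly)
                    h = h + self.a[m, n] * sx * sy + self.b[m, n] * cx * cy
        return h

    def laplacian(self, x, y) -> np.ndarray:
        """Analytic del^2 h — the small-slope total curvature c1 + c2."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lap = np.zeros(np.broadcast(x, y).shape)
        for m in range(3):
            for n in range(3):
                kx = 2 * np.pi * m / self.Lx
                ky = 2 * np.pi * n / self.Ly
                if self.basis == "combined":
                    k2 = kx ** 2 + ky ** 2
                    arg = 2 * np.pi * (m * x / self.Lx + n * y / self.Ly)
                    lap = lap - k2 * (self.a[m, n] * np.sin(arg) + self.b[m, n] * np.cos(arg))
                else:
                    k2 = kx ** 2 + ky ** 2
                    sx, cx = np.sin(kx * x), np.cos(kx * x)
                    sy, cy = np.sin(ky * y), np.cos(ky * y)
                    lap = lap - k2 * (self.a[m, n] * sx * sy + self.b[m, n] * cx * cy)
        return lap


@dataclass
class FluctuationSpectrum:
    """Mode-averaged height-fluctuation power spectrum <|h_q|^2>(q)."""

    q: np.ndarray          # nm^-1, one entry per |q| shell, q > 0
    power: np.ndarray      # nm^2
    se: np.ndarray
    n_frames: int
    area: float            # projected box area, nm^2
    unreliable: bool = False  # set when n_frames == 1 (no ensemble averaging)


@dataclass
class MechanicalModuli:
    KA: Optional[float] = None            # mN/m
    KA_se: Optional[float] = None
    chi_tilt: Optional[float] = None      # kBT/rad^2
    chi_tilt_se: Optional[float] = None
    KC: Optional[float] = None            # kBT
    KC_se: Optional[float] = None
    KC_joule: Optional[float] = None      # J
    chi_spectral: Optional[float] = None  # kBT/nm^2
    chi_spectral_se: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class BendingEnergyProfile:
    z: np.ndarray               # permeant depth, nm
    delta_e_bend: np.ndarray    # kJ/mol
    se: np.ndarray
    mean_total_curvature: np.ndarray  # rms(c1+c2) per window, nm^-1
    flagged: list = field(default_factory=list)  # windows with < 10 frames


@dataclass
class FreeEnergyProfile:
    z: np.ndarray
    dG: np.ndarray              # kJ/mol, dG(z_bulk) = 0
    se: np.ndarray
    metadata: dict = field(default_factory=dict)


@dataclass
class DiffusivityProfile:
    z: np.ndarray
    D: np.ndarray               # internal nm^2/ps
    se: np.ndarray
    diagnostics: list = field(default_factory=list)

    @property
    def D_cm2_s(self) -> np.ndarray:
        from .constants import NM2_PS_TO_CM2_S
        return self.D * NM2_PS_TO_CM2_S


@dataclass
class ResistanceProfile:
    z: np.ndarray
    r_local: np.ndarray         # internal ps/nm^2
    se: np.ndarray

    @property
    def r_local_s_cm2(self) -> np.ndarray:
        from .constants import PS_NM2_TO_S_CM2
        return self.r_local * PS_NM2_TO_S_CM2


@dataclass
class PermeabilityResult:
    P_cm_s: float
    P_se_cm_s: float
    R_total_s_cm: float
    bounds: tuple
    dominant_resistance_z: float
    metadata: dict = field(default_factory=dict)
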