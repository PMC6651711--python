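"""Structural estimators: deuterium order parameter, gauche fraction,
cavity density, and S/Ld phase classification.

The bilayer normal is taken as the z axis throughout.  Analyses that need
whole molecules (C-H vectors, dihedrals) unwrap bonded pairs with the
minimum-image convention, so they are correct whether the source
trajectory stores wrapped or unwrapped coordinates.
"""
from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np

from .datatypes import (CavityProfile, ChainTopology, EstimatorError,
                        FrameEnsemble, GaucheProfile, OrderParameterProfile,
                        ParameterError, PhaseCall)

logger = logging.getLogger(__name__)

# phase thresholds for gel (S) vs liquid-disordered (Ld) classification
SCD_THRESHOLD = 0.3
GAUCHE_THRESHOLD = 0.15
KA_THRESHOLD = 700.0       # mN/m
CHI_THRESHOLD = 13.0       # kBT/rad^2

_TETRA_HALF = math.radians(109.47 / 2.0)
_CH_BOND = 0.109
_METHYL_TILT = math.radians(70.53)  # H cone half-angle about the terminal C-C axis


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors; box broadcast over the last axis."""
    return d - box * np.round(d / box)


def _block_se(values: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error from block means along axis 0 (frames)."""
    n = values.shape[0]
    if n < 2:
        return float("nan")
    nb = min(n_blocks, n)
    blocks = np.array_split(values, nb)
    means = np.array([np.mean(b) for b in blocks])
    return float(np.std(means, ddof=1) / math.sqrt(nb))


# --------------------------------------------------------------------------
# hydrogen reconstruction for united-atom chains
# --------------------------------------------------------------------------

def reconstruct_ch_vectors(positions: np.ndarray, chain: list,
                           box: np.ndarray) -> list:
    """Ideal-geometry C-H unit vectors for every carbon of a united-atom chain.

    Interior CH2 carbons get two hydrogens from the tetrahedral bisector
    construction on (C_{i-1}, C_i, C_{i+1}).  Chain-end carbons get three
    hydrogens on a tetrahedral cone about the terminal C-C axis; the cone
    azimuth is arbitrary because the three-fold average of cos^2(theta) is
    azimuth-independent.  Returns [(carbon_position_index_in_chain,
    unit_vector), ...].
    """
    out = []
    n = len(chain)
    pos = positions
    for k in range(n):
        c = pos[chain[k]]
        if 0 < k < n - 1:
            u = _min_image(pos[chain[k - 1]] - c, box)
            v = _min_image(pos[chain[k + 1]] - c, box)
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            b = -(u + v)
            nb = np.linalg.norm(b)
            if nb < 1e-10:
                continue  # colinear backbone: H plane undefined
            b /= nb
            p = np.cross(u, v)
            np_ = np.linalg.norm(p)
            if np_ < 1e-10:
                continue
            p /= np_
            for sign in (1.0, -1.0):
                d = b * math.cos(_TETRA_HALF) + sign * p * math.sin(_TETRA_HALF)
                out.append((k, d / np.linalg.norm(d)))
        else:
            neighbor = chain[1] if k == 0 else chain[n - 2]
            axis = _min_image(c - pos[neighbor], box)
            axis /= np.linalg.norm(axis)
            ref = np.array([1.0, 0.0, 0.0])
            if abs(axis[0]) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(axis, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis, e1)
            for zeta in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
                d = (axis * math.cos(_METHYL_TILT)
                     + math.sin(_METHYL_TILT) * (e1 * math.cos(zeta) + e2 * math.sin(zeta)))
                out.append((k, d))
    return out


# --------------------------------------------------------------------------
# deuterium order parameter
# --------------------------------------------------------------------------

def deuterium_order(frames: FrameEnsemble, topo: ChainTopology,
                    species: Optional[str] = None,
                    n_blocks: int = 5) -> OrderParameterProfile:
    """|SCD| per carbon index: |<(3 cos^2 theta - 1)/2>| for C-H bonds vs z.

    Averages over both hydrogens of each carbon, all chains of the requested
    species, and all frames; the standard error comes from per-frame block
    means.  With ``topo.ch_bonds == "reconstruct"`` hydrogens are placed by
    ideal geometry on the united-atom backbone.
    """
    chain_sel = [i for i, sp in enumerate(topo.species)
                 if species is None or sp == species]
    if not chain_sel:
        raise ParameterError(f"no chains of species {species!r}")
    n_carbons = len(topo.chains[chain_sel[0]])
    reconstruct = isinstance(topo.ch_bonds, str)

    if not reconstruct:
        # map carbon atom index -> (chain, position) once
        carbon_pos = {}
        for ci in chain_sel:
            for k, atom in enumerate(topo.chains[ci]):
                carbon_pos[atom] = (ci, k)
        bonds = [(c, h, carbon_pos[c][1]) for c, h in topo.ch_bonds
                 if c in carbon_pos]
        if not bonds:
            logger.info("no C-H bonds resolved for species %s; nothing to do", species)
            raise EstimatorError("no C-H bonds for requested species")
        c_idx = np.array([b[0] for b in bonds])
        h_idx = np.array([b[1] for b in bonds])
        k_idx = np.array([b[2] for b in bonds])

    per_frame = np.full((frames.n_frames, n_carbons), np.nan)
    for f in range(frames.n_frames):
        pos = frames.coordinates[f]
        box = frames.box[f]
        sums = np.zeros(n_carbons)
        counts = np.zeros(n_carbons)
        if reconstruct:
            for ci in chain_sel:
                for k, d in reconstruct_ch_vectors(pos, topo.chains[ci], box):
                    cos2 = d[2] ** 2
                    sums[k] += 0.5 * (3.0 * cos2 - 1.0)
                    counts[k] += 1
        else:
            d = _min_image(pos[h_idx] - pos[c_idx], box)
            cos2 = (d[:, 2] / np.linalg.norm(d, axis=1)) ** 2
            p2 = 0.5 * (3.0 * cos2 - 1.0)
            np.add.at(sums, k_idx, p2)
            np.add.at(counts, k_idx, 1)
        skipped = counts == 0
        if skipped.any():
            logger.info("carbons with no hydrogens skipped: %s", np.where(skipped)[0])
        per_frame[f, ~skipped] = sums[~skipped] / counts[~skipped]

    signed = np.nanmean(per_frame, axis=0)
    se = np.array([_block_se(per_frame[:, k][~np.isnan(per_frame[:, k])], n_blocks)
                   for k in range(n_carbons)])
    return OrderParameterProfile(
        species=species or "all", carbon_index=np.arange(n_carbons),
        scd_abs=np.abs(signed), scd_signed=signed, se=se)


# --------------------------------------------------------------------------
# gauche fraction
# --------------------------------------------------------------------------

def _dihedral_angles(pos: np.ndarray, quads: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Signed dihedral angles in degrees for an array of 4-atom index rows."""
    b1 = _min_image(pos[quads[:, 1]] - pos[quads[:, 0]], box)
    b2 = _min_image(pos[quads[:, 2]] - pos[quads[:, 1]], box)
    b3 = _min_image(pos[quads[:, 3]] - pos[quads[:, 2]], box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.degrees(np.arctan2(y, x))


def gauche_fraction(frames: FrameEnsemble, topo: ChainTopology,
                    species: Optional[str] = None,
                    n_blocks: int = 5) -> GaucheProfile:
    """Fraction of gauche conformers per dihedral position along the chain.

    A dihedral is gauche when its angle lies strictly between -120 and +120
    degrees (trans sits at +-180).  Undefined dihedrals (colinear triplets)
    are excluded and counted.
    """
    chain_sel = [i for i, sp in enumerate(topo.species)
                 if species is None or sp == species]
    if not chain_sel:
        raise ParameterError(f"no chains of species {species!r}")
    n_dih = len(topo.chains[chain_sel[0]]) - 3
    quads = []
    for ci in chain_sel:
        chain = topo.chains[ci]
        for i in range(len(chain) - 3):
            quads.append(chain[i:i + 4])
    quads = np.asarray(quads)
    pos_index = np.tile(np.arange(n_dih), len(chain_sel))

    per_frame = np.zeros((frames.n_frames, n_dih))
    valid_per_frame = np.zeros((frames.n_frames, n_dih))
    n_excluded = 0
    for f in range(frames.n_frames):
        pos = frames.coordinates[f]
        box = frames.box[f]
        b2 = _min_image(pos[quads[:, 2]] - pos[quads[:, 1]], box)
        n1 = np.cross(_min_image(pos[quads[:, 1]] - pos[quads[:, 0]], box), b2)
        n2 = np.cross(b2, _min_image(pos[quads[:, 3]] - pos[quads[:, 2]], box))
        degenerate = (np.linalg.norm(n1, axis=1) < 1e-10) | \
                     (np.linalg.norm(n2, axis=1) < 1e-10)
        phi = _dihedral_angles(pos, quads, box)
        gauche = (phi > -120.0) & (phi < 120.0) & ~degenerate
        n_excluded += int(degenerate.sum())
        if degenerate.any():
            logger.info("frame %d: %d undefined dihedrals excluded", f, degenerate.sum())
        np.add.at(per_frame[f], pos_index, gauche.astype(float))
        np.add.at(valid_per_frame[f], pos_index, (~degenerate).astype(float))
    with np.errstate(invalid="ignore"):
        frac_per_frame = per_frame / valid_per_frame
    fraction = np.nansum(per_frame, axis=0) / np.sum(valid_per_frame, axis=0)
    se = np.array([_block_se(frac_per_frame[:, k][~np.isnan(frac_per_frame[:, k])], n_blocks)
                   for k in range(n_dih)])
    return GaucheProfile(species=species or "all",
                         dihedral_index=np.arange(n_dih),
                         fraction=fraction, se=se, n_excluded=n_excluded)


# --------------------------------------------------------------------------
# cavity density
# --------------------------------------------------------------------------

def cavity_density(frames: FrameEnsemble, topo: Optional[ChainTopology] = None,
                   gridsize: float = 0.05, symmetrize: bool = True) -> CavityProfile:
    """Probability that a fine grid cell at depth z contains no atom center.

    A 3-D grid of ``gridsize`` (default 0.05 nm = 0.5 A) spacing is laid over
    the box each frame; a cell is empty when no atom center falls inside it
    (point occupancy).  Pcav(z) is the empty-cell fraction per z slab,
    averaged over frames, with z measured from the frame's center of mass
    and the profile mirrored about z = 0.
    """
    if gridsize <= 0:
        raise ParameterError("gridsize must be positive")
    nz_half_max = int(np.ceil(np.max(frames.box[:, 2]) / gridsize / 2)) + 2
    acc = np.zeros(2 * nz_half_max)
    cnt = np.zeros(2 * nz_half_max)
    for f in range(frames.n_frames):
        pos = frames.coordinates[f]
        box = frames.box[f]
        nx, ny, nz = (int(box[0] // gridsize), int(box[1] // gridsize),
                      int(box[2] // gridsize))
        if nx * gridsize < box[0] - 1e-12 or nz * gridsize < box[2] - 1e-12:
            logger.info("gridsize does not divide the box; trailing partial "
                        "cells dropped")
        wrapped = pos % box
        ix = np.minimum((wrapped[:, 0] / gridsize).astype(int), nx - 1)
        iy = np.minimum((wrapped[:, 1] / gridsize).astype(int), ny - 1)
        iz = np.minimum((wrapped[:, 2] / gridsize).astype(int), nz - 1)
        inside = (ix < nx) & (iy < ny) & (iz < nz)
        lin = (iz[inside] * ny + iy[inside]) * nx + ix[inside]
        occupied_cells = np.unique(lin)
        occ_per_slab = np.bincount(occupied_cells // (nx * ny), minlength=nz)
        pcav_slab = 1.0 - occ_per_slab / (nx * ny)
        z_com = pos[:, 2].mean() if pos.size else box[2] / 2.0
        # shift by a whole number of cells so the slab -> bin map stays
        # injective and exact; the COM is located to within half a cell
        shift = int(np.round(z_com / gridsize))
        rel_bins = np.arange(nz) - shift + nz_half_max
        ok = (rel_bins >= 0) & (rel_bins < acc.size)
        np.add.at(acc, rel_bins[ok], pcav_slab[ok])
        np.add.at(cnt, rel_bins[ok], 1)
    with np.errstate(invalid="ignore"):
        profile = acc / cnt
    centers = (np.arange(acc.size) - nz_half_max + 0.5) * gridsize
    keep = cnt > 0
    centers, profile = centers[keep], profile[keep]
    if symmetrize:
        half = centers >= 0
        z_half = centers[half]
        mirrored = np.interp(-z_half, centers, profile, left=np.nan, right=np.nan)
        sym = np.where(np.isnan(mirrored), profile[half],
                       0.5 * (profile[half] + mirrored))
        return CavityProfile(z=z_half, pcav=sym, gridsize=gridsize)
    return CavityProfile(z=centers, pcav=profile, gridsize=gridsize)


# --------------------------------------------------------------------------
# phase classification
# --------------------------------------------------------------------------

def plateau_slice(n: int) -> slice:
    """Middle alkyl segment used for plateau averages: carbons 4..n-4 (1-based)."""
    return slice(3, max(4, n - 4))


def classify_phase(scd: OrderParameterProfile, gauche: GaucheProfile,
                   KA: Optional[float] = None,
                   chi: Optional[float] = None) -> PhaseCall:
    """Gel (S) vs liquid-disordered (Ld) call from plateau order statistics.

    S requires plateau |SCD| > 0.3 AND plateau gauche fraction < 0.15;
    Ld requires the reverse of both.  Mixed signals yield "conflicting".
    KA > 700 mN/m and chi > 13 kBT/rad^2 are reported as corroborating
    flags, never used to break ties silently.
    """
    scd_plateau = float(np.nanmean(scd.scd_abs[plateau_slice(scd.scd_abs.size)]))
    g_plateau = float(np.nanmean(gauche.fraction[plateau_slice(gauche.fraction.size)]))
    scd_ordered = scd_plateau > SCD_THRESHOLD
    gauche_ordered = g_plateau < GAUCHE_THRESHOLD
    if scd_ordered and gauche_ordered:
        verdict = "S"
    elif not scd_ordered and not gauche_ordered:
        verdict = "Ld"
    else:
        verdict = "conflicting"
    evidence = {
        "scd_plateau": scd_plateau, "scd_threshold": SCD_THRESHOLD,
        "gauche_plateau": g_plateau, "gauche_threshold": GAUCHE_THRESHOLD,
    }
    if KA is not None:
        evidence["KA"] = KA
        evidence["KA_threshold"] = KA_THRESHOLD
        evidence["KA_supports_S"] = KA > KA_THRESHOLD
    if chi is not None:
        evidence["chi_tilt"] = chi
        evidence["chi_threshold"] = CHI_THRESHOLD
        evidence["chi_supports_S"] = chi > CHI_THRESHOLD
    return PhaseCall(verdict=verdict, evidence=evidence)
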