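"""Inhomogeneous solubility-diffusivity (ISD) water-permeation pipeline.

From constrained-simulation force records at fixed depths z this module
computes, in order:

* the permeation free energy ``dG(z)`` by thermodynamic integration of the
  mean constraint forces, referenced to bulk (``dG(z_max) = 0``);
* the local diffusivity ``D(z) = (RT)^2 / integral_0^tc <dF(t) dF(0)> dt``
  from the force autocorrelation function;
* the partition coefficient ``K(z) = exp(-dG/kBT)`` and local resistance
  ``R_local(z) = exp(dG/kBT)/D(z)``;
* the permeability ``P = 1 / integral R_local dz`` over the membrane span.

Internally z is in nm, forces in kJ/mol/nm, times in ps; D and P are
reported in cm^2/s and cm/s.
"""
from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .constants import (NM2_PS_TO_CM2_S, NM_PS_TO_CM_S, PS_NM2_TO_S_CM2,
                        kBT_kJ_mol)
from .datatypes import (DiffusivityProfile, EstimatorError, ForceWindow,
                        FreeEnergyProfile, ParameterError, PermeabilityResult,
                        ResistanceProfile)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# thermodynamic integration
# --------------------------------------------------------------------------

def _pool_windows(windows: Sequence[ForceWindow], burn_in: float = 0.1):
    """Group replicate windows by z; grand mean force and between-replicate se."""
    by_z = defaultdict(list)
    for w in windows:
        series = w.forces[int(burn_in * w.forces.size):]
        by_z[round(float(w.z), 9)].append(float(np.mean(series)))
    zs = np.array(sorted(by_z))
    means = np.array([np.mean(by_z[z]) for z in zs])
    ses = np.array([
        np.std(by_z[z], ddof=1) / math.sqrt(len(by_z[z])) if len(by_z[z]) > 1
        else float("nan") for z in zs])
    return zs, means, ses


def free_energy_TI(windows: Sequence[ForceWindow], burn_in: float = 0.1,
                   method: str = "spline") -> FreeEnergyProfile:
    """dG(z) by thermodynamic integration of mean constraint forces.

    Replicates at equal z are pooled (grand mean; between-replicate scatter
    sets the error bar).  The integral runs from the outermost window (bulk,
    where dG = 0) inward, signed so that a mean force pushing the permeant
    toward bulk yields positive dG inside: dG(z) = + integral_z^zmax <f> dz'.

    ``method="spline"`` integrates the cubic-spline interpolant of <f>(z)
    (default; exact for smooth profiles on the coarse window grid);
    ``method="trapezoid"`` uses the trapezoid rule on the window grid.
    Uncertainties are propagated with trapezoid weights in both cases.
    """
    if len(windows) < 2:
        raise ParameterError("need at least two windows for integration")
    zs, means, ses = _pool_windows(windows, burn_in)
    if zs.size < 2:
        raise ParameterError("need at least two distinct z values")
    if method == "spline" and zs.size >= 4:
        anti = CubicSpline(zs, means).antiderivative()
        dg = float(anti(zs[-1])) - np.asarray(anti(zs))
    elif method in ("spline", "trapezoid"):
        cum = np.concatenate([[0.0], np.cumsum(
            (means[1:] + means[:-1]) * 0.5 * np.diff(zs))])
        dg = cum[-1] - cum
    else:
        raise ParameterError(f"unknown integration method {method!r}")
    # trapezoid quadrature weights for error propagation; dG(z_k) integrates
    # the windows on [z_k, z_max], so each point gets its own weight vector
    # and the reference point carries zero uncertainty by construction
    safe_se = np.where(np.isnan(ses), 0.0, ses)
    var = np.zeros_like(zs)
    for k in range(zs.size - 1):
        w = np.zeros(zs.size - k)
        dzs = np.diff(zs[k:])
        w[:-1] += 0.5 * dzs
        w[1:] += 0.5 * dzs
        var[k] = np.sum((w * safe_se[k:]) ** 2)
    se = np.sqrt(var)
    return FreeEnergyProfile(z=zs, dG=dg, se=se,
                             metadata={"method": method, "burn_in": burn_in,
                                       "reference_z": float(zs[-1])})


def partition_profile(dg: FreeEnergyProfile, temperature: float) -> np.ndarray:
    """K(z) = exp(-dG(z)/kBT); equals 1 where dG = 0 (bulk reference)."""
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    return np.exp(-dg.dG / kBT_kJ_mol(temperature))


# --------------------------------------------------------------------------
# force-autocorrelation diffusivity
# --------------------------------------------------------------------------

def autocorrelation_fft(x: np.ndarray) -> np.ndarray:
    """Unbiased autocorrelation <x(t) x(0)> of a mean-free series via FFT."""
    x = np.asarray(x, dtype=float)
    n = x.size
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n]
    return acf / (n - np.arange(n))


def autocorrelation_direct(x: np.ndarray) -> np.ndarray:
    """O(n^2) reference autocorrelation (oracle for the FFT path)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    return np.array([np.dot(x[:n - k], x[k:]) / (n - k) for k in range(n)])


def _running_integral_cutoff(running: np.ndarray, smooth: int = 5,
                             max_frac: float = 1.0 / 3.0) -> int:
    """Index of the first local maximum of the smoothed running ACF integral."""
    n = running.size
    limit = max(3, int(n * max_frac))
    smoothed = uniform_filter1d(running[:limit], size=smooth, mode="nearest")
    for i in range(1, limit - 1):
        if smoothed[i] >= smoothed[i + 1] and smoothed[i] > 0:
            return i
    # monotone but already flat: accept the plateau even without a local max
    if (smoothed[limit - 1] > 0 and
            smoothed[limit - 1] - smoothed[limit // 2] < 1e-3 * smoothed[limit - 1]):
        return limit - 1
    raise EstimatorError(
        "force ACF does not decay: no plateau of the running integral before "
        f"lag {limit} (of {n} samples)")


def local_diffusivity(window: ForceWindow, burn_in: float = 0.1,
                      smooth: int = 5):
    """D at one depth from the force ACF:  D = (RT)^2 / int_0^tc ACF dt.

    The cutoff tc is the first local maximum of the (5-point smoothed)
    running integral of the autocorrelation of the mean-free force.  Returns
    ``(D_nm2_ps, diagnostics)``.
    """
    series = window.forces[int(burn_in * window.forces.size):]
    return _diffusivity_from_acf(
        autocorrelation_fft(series - series.mean()), window.dt,
        window.temperature, smooth)


def _diffusivity_from_acf(acf: np.ndarray, dt: float, temperature: float,
                          smooth: int = 5):
    if acf[0] <= 0:
        raise EstimatorError("zero force variance: diffusivity undefined")
    corr_time = float(np.trapezoid(
        np.clip(acf[:max(3, np.argmax(acf < 0) or acf.size)], 0, None), dx=dt)
        / acf[0])
    if corr_time < 2 * dt:
        warnings.warn("correlation time barely resolved by dt: the ACF "
                      "integral is dominated by discretization (white-noise "
                      "limit is ill-posed)", stacklevel=2)
    running = np.concatenate([[0.0], np.cumsum((acf[1:] + acf[:-1]) * 0.5 * dt)])
    cut = _running_integral_cutoff(running, smooth=smooth)
    integral = running[cut]
    rt = kBT_kJ_mol(temperature)
    d = rt ** 2 / integral
    diagnostics = {"cutoff_ps": cut * dt, "acf_integral": float(integral),
                   "correlation_time_ps": corr_time}
    return float(d), diagnostics


def diffusivity_profile(windows: Sequence[ForceWindow], burn_in: float = 0.1,
                        smooth: int = 5) -> DiffusivityProfile:
    """D(z) with replicate ACFs averaged per window before integration."""
    by_z = defaultdict(list)
    temps = {}
    for w in windows:
        series = w.forces[int(burn_in * w.forces.size):]
        by_z[round(float(w.z), 9)].append(
            autocorrelation_fft(series - series.mean()))
        temps[round(float(w.z), 9)] = (w.temperature, w.dt)
    zs = np.array(sorted(by_z))
    ds, ses, diags = [], [], []
    for z in zs:
        acfs = by_z[z]
        nmin = min(a.size for a in acfs)
        mean_acf = np.mean([a[:nmin] for a in acfs], axis=0)
        temperature, dt = temps[z]
        d, diag = _diffusivity_from_acf(mean_acf, dt, temperature, smooth)
        if len(acfs) > 1:
            d_each = []
            for a in acfs:
                try:
                    d_each.append(_diffusivity_from_acf(a[:nmin], dt,
                                                        temperature, smooth)[0])
                except EstimatorError:
                    continue
            se = (np.std(d_each, ddof=1) / math.sqrt(len(d_each))
                  if len(d_each) > 1 else float("nan"))
        else:
            se = float("nan")
        diag["z"] = float(z)
        ds.append(d)
        ses.append(se)
        diags.append(diag)
    return DiffusivityProfile(z=zs, D=np.array(ds), se=np.array(ses),
                              diagnostics=diags)


# --------------------------------------------------------------------------
# resistance and permeability
# --------------------------------------------------------------------------

def resistance_profile(dg: FreeEnergyProfile, dz: DiffusivityProfile,
                       temperature: float) -> ResistanceProfile:
    """R_local(z) = exp(dG(z)/kBT) / D(z) on the free-energy grid (ps/nm^2).

    The diffusivity is linearly interpolated when the grids differ (logged).
    Uncertainty by first-order propagation of dG and D errors.
    """
    if np.any(dz.D <= 0):
        raise ParameterError("diffusivity must be positive everywhere")
    if dz.z.shape != dg.z.shape or not np.allclose(dz.z, dg.z):
        logger.info("interpolating D(z) onto the free-energy grid")
        d = np.interp(dg.z, dz.z, dz.D)
        d_se = np.interp(dg.z, dz.z, np.nan_to_num(dz.se))
    else:
        d = dz.D
        d_se = np.nan_to_num(dz.se)
    kbt = kBT_kJ_mol(temperature)
    r = np.exp(dg.dG / kbt) / d
    se = r * np.sqrt((np.nan_to_num(dg.se) / kbt) ** 2 + (d_se / d) ** 2)
    return ResistanceProfile(z=dg.z, r_local=r, se=se)


def permeability(r: ResistanceProfile, bounds: Optional[tuple] = None,
                 mirror: bool = True) -> PermeabilityResult:
    """P = 1 / integral R_local dz across the membrane, in cm/s.

    A one-sided profile (z >= 0, half-membrane) is mirrored about z = 0 when
    ``mirror`` is true, doubling the integral.  Also reports the depth of
    maximum local resistance.
    """
    z = r.z
    if bounds is None:
        bounds = (float(z[0]), float(z[-1]))
    if bounds[0] < z[0] - 1e-9 or bounds[1] > z[-1] + 1e-9:
        raise ParameterError(f"bounds {bounds} outside profile support "
                             f"({z[0]}, {z[-1]})")
    sel = (z >= bounds[0] - 1e-12) & (z <= bounds[1] + 1e-12)
    zs, rs, ses = z[sel], r.r_local[sel], np.nan_to_num(r.se[sel])
    r_half = float(np.trapezoid(rs, zs))  # ps/nm
    w = np.zeros_like(zs)
    w[:-1] += 0.5 * np.diff(zs)
    w[1:] += 0.5 * np.diff(zs)
    var_half = float(np.sum((w * ses) ** 2))
    factor = 2.0 if (mirror and zs[0] >= -1e-12) else 1.0
    r_total = factor * r_half
    r_se = factor * math.sqrt(var_half)
    p_nm_ps = 1.0 / r_total
    p_se = p_nm_ps * r_se / r_total
    thickness = factor * (zs[-1] - zs[0])
    return PermeabilityResult(
        P_cm_s=p_nm_ps * NM_PS_TO_CM_S,
        P_se_cm_s=p_se * NM_PS_TO_CM_S,
        R_total_s_cm=r_total * 1e-5,  # ps/nm -> s/cm
        bounds=(-zs[-1] if factor == 2.0 else zs[0], zs[-1]),
        dominant_resistance_z=float(zs[np.argmax(rs)]),
        metadata={"membrane_thickness_nm": float(thickness),
                  "mirrored": factor == 2.0})


def full_isd_pipeline(windows: Sequence[ForceWindow], temperature: float,
                      burn_in: float = 0.1, ti_method: str = "spline"):
    """Run TI -> D(z) -> R_local(z) -> P in one pass.

    Returns ``(FreeEnergyProfile, DiffusivityProfile, ResistanceProfile,
    PermeabilityResult)``.
    """
    dg = free_energy_TI(windows, burn_in=burn_in, method=ti_method)
    dz = diffusivity_profile(windows, burn_in=burn_in)
    r = resistance_profile(dg, dz, temperature)
    p = permeability(r)
    return dg, dz, r, p
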