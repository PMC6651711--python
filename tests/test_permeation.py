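import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bilayerlab import permeation as perm
from bilayerlab import synthetic as synth
from bilayerlab.constants import NM_PS_TO_CM_S, R_KJ_MOL_K
from bilayerlab.datatypes import (DiffusivityProfile, EstimatorError,
                                  ForceWindow, FreeEnergyProfile,
                                  ParameterError, ResistanceProfile)

RT298 = R_KJ_MOL_K * 298.0


def constant_force_windows(z_values, force, n=200, dt=0.05, temp=298.0):
    return [ForceWindow(z=z, forces=np.full(n, float(force(z))), dt=dt,
                        temperature=temp) for z in z_values]


# ----------------------------------------------------- thermodynamic integration

def test_ti_zero_force_gives_zero_free_energy():
    windows = constant_force_windows(np.linspace(0, 2.8, 15), lambda z: 0.0)
    dg = perm.free_energy_TI(windows)
    np.testing.assert_allclose(dg.dG, 0.0, atol=1e-12)
    assert dg.metadata["reference_z"] == pytest.approx(2.8)


@pytest.mark.parametrize("method", ["spline", "trapezoid"])
def test_ti_constant_force_is_exact(method):
    # <f> = c everywhere: dG(z) = c (z_max - z) exactly for both rules
    c = 4.0
    z = np.linspace(0, 2.8, 15)
    windows = constant_force_windows(z, lambda zz: c)
    dg = perm.free_energy_TI(windows, method=method)
    np.testing.assert_allclose(dg.dG, c * (2.8 - z), atol=1e-10)


def test_ti_linear_force_is_exact():
    # <f> = a z: dG(z) = a (z_max^2 - z^2)/2; exact for the trapezoid rule
    # on any grid and for the spline
    a = 3.0
    z = np.linspace(0, 2.0, 11)
    windows = constant_force_windows(z, lambda zz: a * zz)
    for method in ("spline", "trapezoid"):
        dg = perm.free_energy_TI(windows, method=method)
        np.testing.assert_allclose(dg.dG, a * (2.0 ** 2 - z ** 2) / 2,
                                   atol=1e-9)


def test_ti_gaussian_barrier_spline_beats_trapezoid():
    force_fn, dg_fn = synth.gaussian_barrier(30.0, 1.0, 0.5)
    z = np.round(np.arange(0.0, 2.81, 0.2), 10)
    windows = constant_force_windows(z, lambda zz: float(force_fn(np.array([zz]))[0]))
    truth = dg_fn(z) - dg_fn(z[-1])
    err_spline = np.max(np.abs(perm.free_energy_TI(windows).dG - truth))
    err_trap = np.max(np.abs(
        perm.free_energy_TI(windows, method="trapezoid").dG - truth))
    assert err_spline < err_trap
    assert err_spline < 0.1  # kJ/mol on the 0.2 nm grid


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(min_value=-5, max_value=5), st.floats(min_value=0.1, max_value=3))
def test_ti_linear_in_the_force(scale, offset):
    z = np.linspace(0, 2.0, 9)
    base = perm.free_energy_TI(constant_force_windows(z, lambda zz: zz ** 2)).dG
    shifted = perm.free_energy_TI(
        constant_force_windows(z, lambda zz: scale * zz ** 2 + offset)).dG
    np.testing.assert_allclose(shifted, scale * base + offset * (2.0 - z),
                               atol=1e-8)


def test_ti_requires_two_windows():
    w = constant_force_windows([1.0], lambda z: 0.0)
    with pytest.raises(ParameterError):
        perm.free_energy_TI(w)


def test_ti_pools_replicates_and_reports_scatter():
    z = np.linspace(0, 1.0, 6)
    windows = []
    for rep, bias in enumerate((-1.0, 0.0, 1.0)):
        for zz in z:
            windows.append(ForceWindow(z=zz, forces=np.full(100, 2.0 + bias),
                                       dt=0.05, temperature=298.0,
                                       replicate=rep))
    dg = perm.free_energy_TI(windows, burn_in=0.0)
    # grand mean force is 2.0 exactly
    np.testing.assert_allclose(dg.dG, 2.0 * (1.0 - z), atol=1e-10)
    assert np.all(dg.se[:-1] > 0)
    assert dg.se[-1] == 0.0  # the reference point itself carries no integral


def test_partition_profile_identities():
    z = np.array([0.0, 1.0])
    dg = FreeEnergyProfile(z=z, dG=np.array([30.0, 0.0]), se=np.zeros(2))
    K = perm.partition_profile(dg, 298.0)
    assert K[1] == 1.0
    assert K[0] == pytest.approx(math.exp(-30.0 / RT298))
    with pytest.raises(ParameterError):
        perm.partition_profile(dg, -1.0)


# ----------------------------------------------------- autocorrelation / D

@pytest.mark.parametrize("n", [5, 64, 257, 512])
def test_fft_acf_matches_direct_oracle(n):
    x = np.random.default_rng(n).normal(0, 2, n)
    x -= x.mean()
    np.testing.assert_allclose(perm.autocorrelation_fft(x),
                               perm.autocorrelation_direct(x),
                               rtol=1e-10, atol=1e-12)


def test_diffusivity_recovers_ou_ground_truth():
    spec = synth.SyntheticForceSpec(z_values=[0.0, 1.0], n_steps=200000,
                                    n_replicates=1, seed=12)
    windows = synth.generate_force_windows(spec)
    truth = windows[0].metadata["ground_truth"]["D_true_nm2_ps"]
    d, diag = perm.local_diffusivity(windows[0])
    assert abs(d - truth) / truth < 0.15
    assert diag["cutoff_ps"] > 0


def test_doubling_force_variance_halves_diffusivity():
    # D = (RT)^2 / (sigma^2 tau): the ground-truth law the estimator targets
    def measure(var, seed=31):
        spec = synth.SyntheticForceSpec(z_values=[0.0, 1.0],
                                        force_variance=var, n_steps=100000,
                                        n_replicates=1, seed=seed)
        w = synth.generate_force_windows(spec)[0]
        return perm.local_diffusivity(w)[0]

    ratio = measure(800.0) / measure(400.0)
    assert abs(ratio - 0.5) < 0.1


def test_white_noise_forces_warn():
    rng = np.random.default_rng(0)
    w = ForceWindow(z=0.0, forces=rng.normal(0, 20, 20000), dt=0.05,
                    temperature=298.0)
    with pytest.warns(UserWarning, match="white-noise"):
        perm.local_diffusivity(w)


def test_constant_force_has_no_diffusivity():
    w = ForceWindow(z=0.0, forces=np.full(1000, 3.0), dt=0.05,
                    temperature=298.0)
    with pytest.raises(EstimatorError, match="variance"):
        perm.local_diffusivity(w)


def test_diffusivity_profile_groups_replicates():
    spec = synth.SyntheticForceSpec(z_values=[0.0, 0.5, 1.0], n_steps=20000,
                                    n_replicates=4, seed=13)
    windows = synth.generate_force_windows(spec)
    prof = perm.diffusivity_profile(windows)
    assert prof.z.tolist() == [0.0, 0.5, 1.0]
    truth = windows[0].metadata["ground_truth"]["D_true_nm2_ps"]
    assert np.all(np.abs(prof.D - truth) / truth < 0.25)
    np.testing.assert_allclose(prof.D_cm2_s, prof.D * 1e-2)


# ----------------------------------------------------- resistance

def test_resistance_identities_on_shared_grid():
    z = np.linspace(0, 2.0, 5)
    dg = FreeEnergyProfile(z=z, dG=np.array([RT298, 0.0, 0.0, 0.0, 0.0]),
                           se=np.zeros(5))
    dz = DiffusivityProfile(z=z, D=np.full(5, 0.05), se=np.zeros(5))
    r = perm.resistance_profile(dg, dz, 298.0)
    assert r.r_local[1] == pytest.approx(1.0 / 0.05)
    assert r.r_local[0] == pytest.approx(math.e / 0.05)
    np.testing.assert_allclose(r.r_local_s_cm2, r.r_local * 1e2)


def test_resistance_interpolates_offset_grids():
    zg = np.array([0.0, 1.0, 2.0])
    dg = FreeEnergyProfile(z=zg, dG=np.zeros(3), se=np.zeros(3))
    dz = DiffusivityProfile(z=np.array([0.0, 2.0]),
                            D=np.array([0.02, 0.06]), se=np.zeros(2))
    r = perm.resistance_profile(dg, dz, 298.0)
    # midpoint D interpolates to 0.04
    assert r.r_local[1] == pytest.approx(1.0 / 0.04)


def test_resistance_rejects_nonpositive_diffusivity():
    z = np.array([0.0, 1.0])
    dg = FreeEnergyProfile(z=z, dG=np.zeros(2), se=np.zeros(2))
    dz = DiffusivityProfile(z=z, D=np.array([0.05, 0.0]), se=np.zeros(2))
    with pytest.raises(ParameterError):
        perm.resistance_profile(dg, dz, 298.0)


def test_resistance_monotone_in_free_energy():
    z = np.linspace(0, 1, 4)
    dz = DiffusivityProfile(z=z, D=np.full(4, 0.05), se=np.zeros(4))
    low = perm.resistance_profile(
        FreeEnergyProfile(z=z, dG=np.full(4, 5.0), se=np.zeros(4)), dz, 298.0)
    high = perm.resistance_profile(
        FreeEnergyProfile(z=z, dG=np.full(4, 10.0), se=np.zeros(4)), dz, 298.0)
    assert np.all(high.r_local > low.r_local)


# ----------------------------------------------------- permeability

def test_homogeneous_membrane_permeability_is_d_over_thickness():
    # dG = 0, D = D0 on z in [0, h/2], mirrored: P = D0 / h exactly
    d0, half = 0.05, 2.0
    z = np.linspace(0, half, 21)
    r = ResistanceProfile(z=z, r_local=np.full(21, 1.0 / d0), se=np.zeros(21))
    res = perm.permeability(r)
    expected = d0 / (2 * half)  # nm/ps
    assert res.P_cm_s == pytest.approx(expected * NM_PS_TO_CM_S, rel=1e-12)
    assert res.metadata["mirrored"]
    assert res.metadata["membrane_thickness_nm"] == pytest.approx(2 * half)


def test_square_barrier_matches_analytic_value():
    # dG = G0 on |z| < 1, else 0; D uniform.  R = (2 exp(G0/RT) + 2) / D0
    g0, d0 = 10.0, 0.05
    z = np.arange(0, 2.0 + 1e-9, 0.001)
    dgv = np.where(z < 1.0, g0, 0.0)
    dg = FreeEnergyProfile(z=z, dG=dgv, se=np.zeros_like(z))
    dz = DiffusivityProfile(z=z, D=np.full(z.size, d0), se=np.zeros_like(z))
    r = perm.resistance_profile(dg, dz, 298.0)
    res = perm.permeability(r)
    r_analytic = 2 * (math.exp(g0 / RT298) * 1.0 + 1.0) / d0  # ps/nm
    assert abs(1.0 / res.P_cm_s * NM_PS_TO_CM_S - r_analytic) / r_analytic < 0.005
    assert abs(res.dominant_resistance_z) <= 1.0


def test_doubling_resistance_halves_permeability():
    z = np.linspace(0, 2, 30)
    rl = 20.0 + 5.0 * z
    r1 = perm.permeability(ResistanceProfile(z=z, r_local=rl, se=np.zeros(30)))
    r2 = perm.permeability(ResistanceProfile(z=z, r_local=2 * rl, se=np.zeros(30)))
    assert r2.P_cm_s == pytest.approx(r1.P_cm_s / 2)
    assert r2.R_total_s_cm == pytest.approx(2 * r1.R_total_s_cm)


def test_permeability_bounds_outside_support_rejected():
    z = np.linspace(0, 2, 10)
    r = ResistanceProfile(z=z, r_local=np.full(10, 10.0), se=np.zeros(10))
    with pytest.raises(ParameterError, match="bounds"):
        perm.permeability(r, bounds=(0.0, 5.0))


# ----------------------------------------------------- end-to-end

def test_full_isd_pipeline_recovers_analytic_permeability():
    force_fn, dg_fn = synth.gaussian_barrier(30.0, 1.0, 0.5)
    spec = synth.SyntheticForceSpec(mean_force_profile=force_fn, seed=14)
    windows = synth.generate_force_windows(spec)
    dg, dz, r, p = perm.full_isd_pipeline(windows, 298.0)

    # analytic reference on a fine grid with the true D
    zf = np.linspace(0, 2.8, 2801)
    g = dg_fn(zf) - dg_fn(zf[-1])
    d_true = windows[0].metadata["ground_truth"]["D_true_nm2_ps"]
    r_true = 2 * np.trapezoid(np.exp(g / RT298) / d_true, zf)
    p_true = 1.0 / r_true * NM_PS_TO_CM_S
    assert abs(p.P_cm_s - p_true) / p_true < 0.20
    # barrier height from TI within noise
    assert abs(dg.dG.max() - g.max()) < 1.5
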