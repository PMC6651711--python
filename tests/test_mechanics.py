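import math

import numpy as np
import pytest

from bilayerlab import mechanics as mech
from bilayerlab import synthetic as synth
from bilayerlab.constants import kBT_kJ_mol
from bilayerlab.datatypes import (ChainTopology, EstimatorError, FrameEnsemble,
                                  HeightField, ParameterError)


# ----------------------------------------------------- area compressibility

def test_ka_recovers_generator_truth():
    areas = synth.generate_area_series(0.25, 700.0, 64, 298.0, 100000, seed=2)
    ka, se = mech.area_compressibility(areas, 298.0)
    assert abs(ka - 700.0) <= max(3 * se, 0.03 * 700.0)


def test_ka_scales_linearly_with_temperature():
    areas = synth.generate_area_series(0.25, 700.0, 64, 298.0, 5000, seed=3)
    ka1, _ = mech.area_compressibility(areas, 298.0)
    ka2, _ = mech.area_compressibility(areas, 596.0)
    assert ka2 / ka1 == pytest.approx(2.0, rel=1e-12)


def test_ka_rigid_series_is_infinite():
    from bilayerlab.datatypes import AreaSeries
    areas = AreaSeries(area_per_molecule=np.full(500, 0.25), n_molecules=64)
    ka, se = mech.area_compressibility(areas, 298.0)
    assert math.isinf(ka) and math.isnan(se)


def test_ka_short_series_warns():
    areas = synth.generate_area_series(0.25, 700.0, 64, 298.0, 50, seed=4)
    with pytest.warns(UserWarning, match="unreliable"):
        mech.area_compressibility(areas, 298.0)


# ----------------------------------------------------- tilt modulus

def make_tilted_frame(angles_deg):
    """One 4-carbon chain per angle, tilted in the x-z plane."""
    pos, chains, leaflet = [], [], []
    for i, a in enumerate(angles_deg):
        a = math.radians(a)
        d = np.array([math.sin(a), 0.0, math.cos(a)])
        base = np.array([1.0 + i, 1.0, 1.0])
        atoms = [base + 0.13 * k * d for k in range(4)]
        chains.append(list(range(4 * i, 4 * i + 4)))
        leaflet.append("upper")
        pos.extend(atoms)
    topo = ChainTopology(chains=chains, ch_bonds=[], dihedrals=[],
                         leaflet=leaflet,
                         headgroup_atoms=[c[0] for c in chains])
    frames = FrameEnsemble(np.asarray(pos)[None],
                           np.array([[20.0, 20.0, 5.0]]), np.zeros(1))
    return frames, topo


def test_chain_tilt_angles_known_geometry():
    frames, topo = make_tilted_frame([0.0, 30.0, 60.0])
    angles = mech.chain_tilt_angles(frames, topo)
    np.testing.assert_allclose(np.degrees(angles), [0.0, 30.0, 60.0],
                               atol=1e-9)


def test_chain_tilt_angle_folded_for_lower_leaflet():
    frames, topo = make_tilted_frame([150.0])  # points mostly downward
    angles = mech.chain_tilt_angles(frames, topo)
    np.testing.assert_allclose(np.degrees(angles), [30.0], atol=1e-9)


def test_tilt_modulus_recovers_generator_truth():
    alpha = synth.generate_tilt_angles(13.0, 0.35, 200000, seed=5)
    chi, chi_se, dist = mech.tilt_modulus_from_angles(alpha)
    assert abs(chi - 13.0) / 13.0 < 0.10
    assert abs(dist.alpha0 - 0.35) < 0.05


def test_tilt_modulus_uniform_hemisphere_is_soft():
    # chi_true = 0 means P(alpha) ∝ sin(alpha): the inverted free energy is
    # flat, so the fitted curvature must be small compared to an ordered phase
    alpha = synth.generate_tilt_angles(0.0, 0.0, 200000, seed=6)
    chi, _, _ = mech.tilt_modulus_from_angles(alpha)
    assert abs(chi) < 1.0


def test_tilt_modulus_degenerate_input_raises():
    with pytest.raises(EstimatorError, match="degenerate"):
        mech.tilt_modulus_from_angles(np.full(1000, 0.3))
    with pytest.raises(EstimatorError, match="few"):
        mech.tilt_modulus_from_angles(np.linspace(0.1, 0.5, 10))


# ----------------------------------------------------- height-field fitting

def test_fit_height_field_flat_surface():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(0, 10, 40), rng.uniform(0, 10, 40),
                           np.full(40, 1.7)])
    hf = mech.fit_height_field(pts, 10.0, 10.0)
    assert hf.residual_rms < 1e-10
    np.testing.assert_allclose(hf.evaluate(3.0, 7.0), 1.7, atol=1e-9)
    np.testing.assert_allclose(hf.laplacian(3.0, 7.0), 0.0, atol=1e-9)


def test_fit_height_field_recovers_in_basis_surface():
    rng = np.random.default_rng(1)
    L = 12.0
    true = HeightField(a=np.zeros((3, 3)), b=np.zeros((3, 3)), Lx=L, Ly=L)
    true.a[1, 0] = 0.4
    true.b[0, 2] = -0.2
    true.a[2, 1] = 0.1
    pts_xy = rng.uniform(0, L, (60, 2))
    z = true.evaluate(pts_xy[:, 0], pts_xy[:, 1])
    hf = mech.fit_height_field(np.column_stack([pts_xy, z]), L, L)
    assert hf.residual_rms < 1e-9
    xg, yg = np.meshgrid(np.linspace(0, L, 9), np.linspace(0, L, 9))
    np.testing.assert_allclose(hf.evaluate(xg, yg), true.evaluate(xg, yg),
                               atol=1e-8)


def test_fit_height_field_too_few_points():
    pts = np.random.default_rng(2).uniform(0, 5, (17, 3))
    with pytest.raises(ParameterError, match="18"):
        mech.fit_height_field(pts, 5.0, 5.0)


def test_fit_height_field_degenerate_points_raise():
    # all points on one line: the 2-D basis cannot be resolved
    t = np.linspace(0, 5, 30)
    pts = np.column_stack([t, t, np.zeros(30)])
    with pytest.raises(EstimatorError, match="rank"):
        mech.fit_height_field(pts, 5.0, 5.0)


# ----------------------------------------------------- fluctuation spectrum

def brute_force_spectrum(h, L):
    """O(n^4) DFT oracle: shell-pooled per-mode power, h_q = DFT(h)/n^2."""
    n = h.shape[0]
    amp = np.zeros((n, n), dtype=complex)
    for kx in range(n):
        for ky in range(n):
            s = 0.0
            for x in range(n):
                for y in range(n):
                    s += h[x, y] * np.exp(-2j * np.pi * (kx * x + ky * y) / n)
            amp[kx, ky] = s / n ** 2
    power = np.abs(amp) ** 2
    q = 2 * np.pi * np.fft.fftfreq(n, d=L / n)
    qmag = np.round(np.sqrt(q[:, None] ** 2 + q[None, :] ** 2), 9)
    shells = np.unique(qmag)
    shells = shells[shells > 0]
    pooled = np.array([power[qmag == s].mean() for s in shells])
    return shells, pooled


def test_height_spectrum_matches_dft_oracle():
    rng = np.random.default_rng(7)
    h = rng.normal(0, 0.1, (4, 4))
    L = 8.0
    spec = mech.height_spectrum(h, Lx=L, Ly=L)
    q_ref, p_ref = brute_force_spectrum(h, L)
    np.testing.assert_allclose(spec.q, q_ref, atol=1e-9)
    np.testing.assert_allclose(spec.power, p_ref, rtol=1e-10)


def test_height_spectrum_requires_box_for_raw_arrays():
    with pytest.raises(ParameterError):
        mech.height_spectrum(np.zeros((2, 8, 8)))


@pytest.mark.parametrize("chi_true", [0.0, 5.0])
def test_kc_recovered_from_synthetic_spectrum(chi_true):
    spec = synth.SyntheticSurfaceSpec(KC_true=20.0, chi_true=chi_true,
                                      n_frames=2000, seed=8)
    surf = synth.generate_height_frames(spec)
    kc, kc_se, chi, chi_se, _, diag = mech.bending_modulus_spectrum(surf)
    assert abs(kc - 20.0) / 20.0 < 0.10
    if chi_true > 0:
        assert abs(chi - chi_true) / chi_true < 0.25
    else:
        assert chi < 1.0
    assert diag["r_squared"] > 0.99


def test_flat_surfaces_unfittable():
    from bilayerlab.synthetic import SurfaceEnsemble
    flat = SurfaceEnsemble(np.zeros((50, 16, 16)), 20.0, 20.0)
    with pytest.raises(EstimatorError, match="zero"):
        mech.bending_modulus_spectrum(flat)


def test_kc_from_trajectory_headgroups_matches_surface_route():
    """Headgroup positions sampled from known surfaces recover the fields."""
    rng = np.random.default_rng(9)
    L, n_frames = 20.0, 40
    # build frames whose head atoms lie exactly on an in-basis surface
    n_heads = 100
    coords = []
    fields = []
    for f in range(n_frames):
        hf = HeightField(a=rng.normal(0, 0.05, (3, 3)),
                         b=rng.normal(0, 0.05, (3, 3)), Lx=L, Ly=L)
        hf.a[0, 0] = 0.0
        fields.append(hf)
        xy_u = rng.uniform(0, L, (n_heads, 2))
        xy_l = rng.uniform(0, L, (n_heads, 2))
        upper = np.column_stack([xy_u, 2.0 + hf.evaluate(xy_u[:, 0], xy_u[:, 1])])
        lower = np.column_stack([xy_l, -2.0 + hf.evaluate(xy_l[:, 0], xy_l[:, 1])])
        heads = np.vstack([upper, lower])
        # each head leads a 4-atom stub chain hanging toward the midplane
        stub = np.zeros((2 * n_heads, 4, 3))
        for i, (h, sgn) in enumerate(zip(heads,
                                         [-1.0] * n_heads + [1.0] * n_heads)):
            for k in range(4):
                stub[i, k] = h + np.array([0.0, 0.0, sgn * 0.13 * k])
        coords.append(stub.reshape(-1, 3))
    frames = FrameEnsemble(np.asarray(coords),
                           np.tile([L, L, 6.0], (n_frames, 1)),
                           np.arange(n_frames, dtype=float))
    topo = ChainTopology(
        chains=[list(range(4 * i, 4 * i + 4)) for i in range(2 * n_heads)],
        ch_bonds=[], dihedrals=[],
        leaflet=["upper"] * n_heads + ["lower"] * n_heads,
        headgroup_atoms=[4 * i for i in range(2 * n_heads)])
    grids, Lx, Ly = mech.midsurface_grids(frames, topo, n_grid=16)
    xs = (np.arange(16) + 0.5) * L / 16
    X, Y = np.meshgrid(xs, ys := xs, indexing="ij")
    for f in (0, n_frames // 2, n_frames - 1):
        expected = fields[f].evaluate(X, Y)
        np.testing.assert_allclose(grids[f], expected - expected.mean(),
                                   atol=1e-6)


# ----------------------------------------------------- bending energy

def single_mode(amp, L=20.0):
    hf = HeightField(a=np.zeros((3, 3)), b=np.zeros((3, 3)), Lx=L, Ly=L)
    hf.a[1, 0] = amp
    return hf


def test_bending_energy_flat_is_zero():
    hf = HeightField(a=np.zeros((3, 3)), b=np.zeros((3, 3)), Lx=20.0, Ly=20.0)
    hf.b[0, 0] = 1.5  # constant offset has no curvature
    assert mech.bending_energy(hf, KC=20.0) == 0.0


def test_bending_energy_single_mode_closed_form():
    amp, L, KC = 0.3, 20.0, 20.0
    e = mech.bending_energy(single_mode(amp, L), KC)
    expected = 0.5 * KC * kBT_kJ_mol(298.0) * amp ** 2 * (2 * np.pi / L) ** 4 \
        * L ** 2 / 2.0
    assert abs(e - expected) / expected < 1e-3


def test_bending_energy_linear_in_kc_quadratic_in_amplitude():
    e1 = mech.bending_energy(single_mode(0.2), 10.0)
    assert mech.bending_energy(single_mode(0.2), 20.0) == pytest.approx(2 * e1)
    assert mech.bending_energy(single_mode(0.4), 10.0) == pytest.approx(4 * e1)


def test_bending_energy_rejects_nonpositive_kc():
    with pytest.raises(ParameterError):
        mech.bending_energy(single_mode(0.2), 0.0)


def test_monge_curvature_close_to_small_slope_for_gentle_surface():
    hf = single_mode(0.05)  # max slope ~ 0.016: corrections are O(slope^2)
    e_ss = mech.bending_energy(hf, 20.0, curvature="small_slope")
    e_mg = mech.bending_energy(hf, 20.0, curvature="monge")
    assert abs(e_mg - e_ss) / e_ss < 1e-3


def test_bending_profile_peak_and_flags():
    flat = HeightField(a=np.zeros((3, 3)), b=np.zeros((3, 3)),
                       Lx=20.0, Ly=20.0)
    fields = {0.0: [single_mode(0.3)] * 12,
              1.0: [single_mode(0.15)] * 12,
              2.8: [flat] * 3}
    prof = mech.bending_profile(fields, KC=20.0)
    assert prof.z.tolist() == [0.0, 1.0, 2.8]
    assert prof.delta_e_bend[2] == 0.0
    # quadratic in curvature amplitude
    assert prof.delta_e_bend[0] == pytest.approx(4 * prof.delta_e_bend[1])
    assert prof.flagged == [2.8]
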