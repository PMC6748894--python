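"""Metric oracles on synthetic curves and affine displacement fields."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from fibernet import presets
from fibernet.mechanics import SimulationResult, StressStretchCurve
from fibernet.metrics import (
    MetricError,
    affine_angle_deg,
    average_waviness,
    final_slope,
    local_strain_state,
    non_affinity,
    orientation_evolution,
    recruitment_stretch,
    rupture_probability,
    state_at_stress,
)
from fibernet.network import BoxDomain, generate_network

BOX = BoxDomain(300.0, 300.0, 60.0)


def small_net(seed=0):
    return generate_network(
        presets.MEASURED_MIXTURE,
        presets.MEASURED_WAVINESS,
        target_vf=0.05,
        box=BOX,
        r_phys=2.0,
        l_seg=15.0,
        seed=seed,
    )


def affine_result(net, lams, lam_ts):
    """A SimulationResult whose displacement field is exactly affine."""
    X = net.nodes
    c = np.array([0.0, BOX.Ly / 2.0, 0.0])
    T = len(lams)
    disp = np.zeros((T, len(X), 3))
    for t, (lam, lt) in enumerate(zip(lams, lam_ts)):
        F = np.diag([lam, lt, 1.0])
        disp[t] = (X - c) @ F.T + c - X
    lams = np.asarray(lams, dtype=float)
    pk1 = lams - 1.0
    return SimulationResult(
        stretch=lams,
        force=pk1 * BOX.Ly * BOX.Lz,
        pk1=pk1,
        displacements=disp,
        seg_strain=np.zeros((T, len(net.segments))),
        seg_stress=np.zeros((T, len(net.segments))),
        pivot=(np.asarray(lam_ts) - 1.0) * BOX.Ly / 2.0,
        network=net,
        metadata={},
    )


class TestCurveMetrics:
    def test_final_slope_linear_curve_exact(self):
        lam = np.linspace(1.0, 2.0, 41)
        curve = StressStretchCurve(lam, 3.0 * lam - 3.0)
        assert abs(final_slope(curve) - 3.0) < 1e-12

    def test_final_slope_uses_last_ten_percent(self):
        lam = np.linspace(1.0, 2.0, 101)
        sig = np.where(lam < 1.9, 0.0, 10.0 * (lam - 1.9))
        assert abs(final_slope(curve := StressStretchCurve(lam, sig)) - 10.0) < 1e-9

    def test_final_slope_needs_three_points(self):
        lam = np.array([1.0, 1.5, 2.0])
        with pytest.raises(MetricError):
            final_slope(StressStretchCurve(lam, lam))

    def test_recruitment_bilinear(self):
        lam = np.linspace(1.0, 2.0, 51)
        sig = np.where(lam < 1.24, 0.0, 5.0 * (lam - 1.24))
        r = recruitment_stretch(StressStretchCurve(lam, sig))
        assert abs(r - 1.24) < 0.03

    def test_recruitment_linear_is_nan_with_warning(self):
        lam = np.linspace(1.0, 2.0, 51)
        with pytest.warns(UserWarning):
            r = recruitment_stretch(StressStretchCurve(lam, 2.0 * lam))
        assert math.isnan(r)

    def test_curve_rejects_nonmonotone_stretch(self):
        lam = np.array([1.0, 1.2, 1.1, 1.4, 1.5, 1.6, 1.7])
        with pytest.raises(ValueError):
            StressStretchCurve(lam, lam)


class TestOrientation:
    def test_affine_field_matches_affine_angle_rule(self):
        net = small_net(1)
        lams = [1.0, 1.5, 2.0]
        lam_ts = [1.0, 1.5 ** -0.5, 2.0 ** -0.5]
        evo = orientation_evolution(affine_result(net, lams, lam_ts))
        theta0 = evo.angles_deg[0]
        for t in (1, 2):
            pred = affine_angle_deg(theta0, lams[t], lam_ts[t])
            assert np.max(np.abs(evo.angles_deg[t] - pred)) < 1e-9

    def test_no_deformation_zero_reorientation(self):
        net = small_net(2)
        evo = orientation_evolution(affine_result(net, [1.0, 1.0], [1.0, 1.0]))
        assert np.max(np.abs(evo.reorientation_percent)) < 1e-9

    def test_affine_angle_examples(self):
        assert abs(affine_angle_deg(45.0, 2.0, 0.5) - math.degrees(math.atan(0.25))) < 1e-12
        assert affine_angle_deg(0.0, 2.0, 0.5) == 0.0


class TestWavinessAndNonAffinity:
    def test_initial_average_waviness_matches_geometry(self):
        from fibernet.network import fiber_waviness

        net = small_net(3)
        w = average_waviness(affine_result(net, [1.0], [1.0]))
        expected = np.mean([fiber_waviness(f) for f in net.fibers])
        assert abs(w[0] - expected) < 1e-12

    def test_stretching_straightens(self):
        net = small_net(3)
        w = average_waviness(affine_result(net, [1.0, 1.6], [1.0, 1.6 ** -0.5]))
        assert w[1] > w[0]
        assert np.all(w <= 1.0 + 1e-12)

    def test_affine_field_has_zero_non_affinity(self):
        net = small_net(4)
        res = affine_result(net, [1.0, 1.5, 2.0], [1.0, 1.5 ** -0.5, 2.0 ** -0.5])
        na = non_affinity(res, r=40.0)
        assert np.max(np.abs(na)) < 1e-18
        assert "na_excluded_nodes" in res.metadata

    def test_rigid_rotation_registers_omega(self):
        X2 = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]])
        phi = 1e-3
        G = np.array([[0.0, -phi], [phi, 0.0]])  # u = G x (small rotation)
        U2 = X2 @ G.T
        E = local_strain_state(X2, U2, 4, [0, 1, 2, 3])
        # (eps11, eps22, eps12, omega12) with omega12 = (u1,2 - u2,1)/2
        assert np.allclose(E, [0.0, 0.0, 0.0, -phi], atol=1e-15)

    def test_local_strain_state_exact_for_linear_field(self):
        rng = np.random.default_rng(5)
        X2 = rng.uniform(0, 10, size=(12, 2))
        G = np.array([[0.03, 0.01], [-0.02, 0.05]])  # du_i/dx_j
        U2 = X2 @ G.T
        E = local_strain_state(X2, U2, 0, list(range(1, 12)))
        expected = [G[0, 0], G[1, 1],
                    0.5 * (G[0, 1] + G[1, 0]),
                    0.5 * (G[0, 1] - G[1, 0])]
        assert np.allclose(E, expected, atol=1e-12)


def synthetic_state_result(net):
    lam = np.linspace(1.0, 2.0, 11)
    T = len(lam)
    M = 4
    seg_strain = np.outer(lam - 1.0, np.arange(1, M + 1) * 0.05)
    seg_stress = 100.0 * seg_strain
    return SimulationResult(
        stretch=lam,
        force=np.linspace(0, 10, T),
        pk1=np.linspace(0, 2.0, T),
        displacements=np.zeros((T, len(net.nodes), 3)),
        seg_strain=seg_strain,
        seg_stress=seg_stress,
        pivot=np.zeros(T),
        network=net,
        metadata={},
    )


class TestStateAtStress:
    def test_interpolation_exact_between_grid_points(self):
        net = small_net(5)
        res = synthetic_state_result(net)
        st = state_at_stress(res, 0.3)  # pk1 grid step is 0.2
        # linear-in-pk1 synthetic data: interpolation is exact
        lam_expected = float(np.interp(0.3, res.pk1, res.stretch))
        assert abs(st.stretch - lam_expected) < 1e-12
        eps_expected = (lam_expected - 1.0) * np.arange(1, 5) * 0.05
        assert np.allclose(st.seg_strain, eps_expected, atol=1e-12)
        assert np.allclose(st.seg_stress, 100.0 * st.seg_strain, atol=1e-10)

    def test_rejects_target_beyond_curve(self):
        net = small_net(5)
        res = synthetic_state_result(net)
        with pytest.raises(MetricError):
            state_at_stress(res, 5.0)


class TestRupture:
    def test_beta_tail_matches_closed_form(self):
        rng = np.random.default_rng(11)
        a, b, scale = 3.0, 5.0, 0.2
        x = rng.beta(a, b, size=20000) * scale
        thr = 0.10
        out = rupture_probability(x, threshold=thr)
        closed = float(stats.beta.sf(thr / scale, a, b))
        assert out.fitted
        # sampling noise floor: sd of the empirical fraction is ~0.003
        assert abs(out.probability - closed) < 0.01
        assert abs(out.empirical - closed) < 0.01
        assert abs(out.probability - out.empirical) < 0.005

    def test_zero_threshold_is_certain(self):
        assert rupture_probability([0.01, 0.02], threshold=0.0).probability == 1.0

    def test_degenerate_sample_falls_back_to_empirical(self):
        out = rupture_probability(np.full(100, 0.2), threshold=0.1)
        assert not out.fitted
        assert out.probability == 1.0

    def test_empty_raises(self):
        with pytest.raises(MetricError):
            rupture_probability([])
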