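"""Solver oracles: closed forms, energy consistency, brute-force minimization."""

import math

import numpy as np
import pytest

from fibernet import presets
from fibernet.distributions import OrientationMixture, WavinessDist
from fibernet.mechanics import (
    BoundarySpec,
    MaterialParams,
    SolverConfig,
    StressStretchCurve,
    apply_boundary_conditions,
    assemble_model,
    pk1_curve,
    simulate_network,
    solve_uniaxial,
)
from fibernet.network import BoxDomain, generate_network

STRAIGHT_MIX = OrientationMixture.from_degrees(0.0, 0.0, 500.0, 500.0, 0.5)
STRAIGHT_WAV = WavinessDist(1e6, 1e-3)


def straight_fiber_net(seed=3, box=None):
    box = box or BoxDomain(500.0, 500.0, 100.0)
    net = generate_network(
        STRAIGHT_MIX, STRAIGHT_WAV, target_vf=1e-4, box=box,
        r_phys=5.0, l_seg=25.0, seed=seed,
    )
    assert net.n_fibers == 1
    return net


class TestMaterialParams:
    def test_EA_closed_form_and_r_eff_invariance(self):
        ea = MaterialParams(E_fiber=297.0, r_phys=5.0, r_eff=0.1).EA
        assert abs(ea - 297.0 * math.pi * 25.0) < 1e-9
        ea2 = MaterialParams(E_fiber=297.0, r_phys=5.0, r_eff=0.2).EA
        assert ea == ea2

    def test_bending_ratio_under_radius_substitution(self):
        full = MaterialParams(E_fiber=297.0, r_phys=5.0, r_eff=5.0)
        reduced = MaterialParams(E_fiber=297.0, r_phys=5.0, r_eff=0.1)
        assert abs(reduced.EI_eff / full.EI_eff - (0.1 / 5.0) ** 2) < 1e-12

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            MaterialParams(E_fiber=-1.0)
        with pytest.raises(ValueError):
            MaterialParams(E_fiber=1.0, r_phys=1.0, r_eff=2.0)


class TestClosedFormOracles:
    def test_straight_fiber_force(self):
        net = straight_fiber_net()
        res = simulate_network(
            net, E_fiber=100.0, K=1.0, stretch_max=1.5,
            cfg=SolverConfig(n_increments=10),
        )
        EA = 100.0 * math.pi * 25.0
        assert abs(res.force[-1] - EA * 0.5) / (EA * 0.5) < 0.01

    def test_zigzag_recruits_at_inverse_waviness(self):
        wav = WavinessDist(0.8e5, 0.2e5)  # concentrated near W = 0.8
        net = generate_network(
            STRAIGHT_MIX, wav, target_vf=1e-4,
            box=BoxDomain(500.0, 500.0, 100.0),
            r_phys=5.0, l_seg=25.0, seed=5, min_segments=4,
        )
        res = simulate_network(
            net, E_fiber=50.0, K=1.0, stretch_max=1.5,
            cfg=SolverConfig(n_increments=30),
        )
        frac = res.force / res.force[-1]
        lam_5pct = float(np.interp(0.05, frac, res.stretch))
        assert abs(lam_5pct - 1.0 / net.fibers[0].waviness) < 0.05

    def test_rigid_translation_zero_internal_forces(self):
        net = straight_fiber_net()
        model = assemble_model(net, MaterialParams(E_fiber=100.0))
        x = model.X + np.array([3.0, -2.0])
        f = model.internal_forces(x)
        assert np.max(np.abs(f)) < 1e-9 * model.EA.mean()

    def test_pk1_arithmetic(self):
        curve = StressStretchCurve(np.array([1.0, 2.0]), np.array([0.0, 2.0]))
        net = straight_fiber_net()
        res = simulate_network(
            net, E_fiber=100.0, K=1.0, stretch_max=1.2,
            cfg=SolverConfig(n_increments=4),
        )
        A0 = 500.0 * 100.0
        c = pk1_curve(res)
        assert np.allclose(c.stress, res.force / A0)
        assert res.pk1[0] == 0.0


TINY_MIX = OrientationMixture.from_degrees(-25.0, 25.0, 30.0, 30.0, 0.5)


def tiny_net(seed, n_target=3):
    """A network of a few fibers spanning the loading faces."""
    box = BoxDomain(200.0, 200.0, 40.0)
    wav = WavinessDist.from_mean(0.8, total=presets.WAVINESS_TOTAL)
    net = generate_network(
        TINY_MIX, wav,
        target_vf=n_target * 6.5e-3,
        box=box, r_phys=5.0, l_seg=20.0, seed=seed,
    )
    assert net.n_fibers <= 5
    return net


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", [1, 4])
    def test_energy_minimization_matches_solver(self, seed):
        """Independent check: L-BFGS on the total potential (same BC)."""
        from scipy.optimize import minimize

        net = tiny_net(seed)
        lam = 1.6
        mat = MaterialParams(E_fiber=80.0)
        model = assemble_model(net, mat)
        spec = BoundarySpec(u_circ=(lam - 1.0) * net.box.Lx, K=2.0)
        model = apply_boundary_conditions(model, spec)
        res = solve_uniaxial(model, SolverConfig(n_increments=24))

        # freeze the clamp ramp at the solver's converged pivot and minimize
        # the same potential over the reduced unknowns with scipy
        p = res.pivot[-1]
        n_dof = 2 * model.X.shape[0]
        g = np.zeros(n_dof)
        g[2 * model.loaded_nodes] = spec.u_circ
        g[2 * model.clamp_nodes + 1] = model.c_clamp * p
        d_aff = (lam ** -0.5 - 1.0) * net.box.Ly / 2.0
        pc = model.pivot_col

        def pot(q):
            u = model.T @ q + g
            x = model.X + u.reshape(-1, 2)
            e = model.strain_energy(x)
            return e + 0.5 * spec.K * (q[pc] - d_aff) ** 2

        def grad(q):
            u = model.T @ q + g
            x = model.X + u.reshape(-1, 2)
            r = model.Tt @ model.internal_forces(x)
            r[pc] += spec.K * (q[pc] - d_aff)
            return r

        q0 = np.zeros(model.T.shape[1])
        q0[: len(model.free_dofs)] = (
            (model.T @ _affine_guess(model, lam) )[model.free_dofs]
            if False else _affine_guess(model, lam)[model.free_dofs]
        )
        q0[pc] = d_aff
        out = minimize(pot, q0, jac=grad, method="L-BFGS-B",
                       options={"maxiter": 20000, "ftol": 1e-14,
                                "gtol": 1e-10})
        u = model.T @ out.x + g
        x = model.X + u.reshape(-1, 2)
        f = model.internal_forces(x)
        F_ref = float(np.sum(f[2 * model.loaded_nodes]))
        F_solver = res.force[-1]
        assert abs(F_solver - F_ref) / max(abs(F_ref), 1e-9) < 0.01


def _affine_guess(model, lam):
    X = model.X
    box = model.net.box
    u = np.empty(2 * X.shape[0])
    u[0::2] = (lam - 1.0) * X[:, 0]
    u[1::2] = (lam ** -0.5 - 1.0) * (X[:, 1] - box.Ly / 2.0)
    return u


class TestGlobalBehaviour:
    def test_energy_consistency(self):
        net = tiny_net(1)
        res = simulate_network(
            net, E_fiber=80.0, K=2.0, stretch_max=1.6,
            cfg=SolverConfig(n_increments=40),
        )
        w = res.metadata["external_work"]
        e = res.metadata["stored_energy"]
        assert abs(w - e) / max(e, 1e-12) < 0.02

    def test_r_eff_invariance_of_stress(self):
        box = BoxDomain(200.0, 200.0, 40.0)
        wav = WavinessDist.from_mean(0.8, total=presets.WAVINESS_TOTAL)
        net = generate_network(
            presets.MEASURED_MIXTURE, wav, target_vf=0.2,
            box=box, r_phys=5.0, l_seg=20.0, seed=8,
        )
        stresses = []
        for r_eff in (0.05, 0.2):
            res = simulate_network(
                net, E_fiber=100.0, K=2.0, stretch_max=1.8, r_eff=r_eff,
                cfg=SolverConfig(n_increments=40),
            )
            stresses.append(res.pk1[-1])
        assert abs(stresses[0] - stresses[1]) / stresses[1] < 0.005

    def test_monotone_stretch_and_zero_initial_force(self):
        net = tiny_net(4)
        res = simulate_network(
            net, E_fiber=80.0, K=2.0, stretch_max=1.5,
            cfg=SolverConfig(n_increments=10),
        )
        assert np.all(np.diff(res.stretch) > 0)
        assert abs(res.force[0]) < 1e-9

    def test_affine_limit_of_stiff_connector(self):
        net = tiny_net(1)
        res = simulate_network(
            net, E_fiber=80.0, K=1e5, stretch_max=2.0,
            cfg=SolverConfig(n_increments=20),
        )
        u_aff = (2.0 ** -0.5 - 1.0) * net.box.Ly / 2.0
        assert abs(res.pivot[-1] - u_aff) < 0.01 * abs(u_aff)
        # scaled to a 500 um wide box: (1 - 2**-0.5) * 250 = 73.22 um
        assert abs(abs(u_aff) * 500.0 / net.box.Ly - 73.22) < 0.05

    def test_kinematic_boundary_stretch_of_two(self):
        box = BoxDomain(500.0, 500.0, 100.0)
        net = straight_fiber_net(box=box)
        res = simulate_network(
            net, E_fiber=100.0, K=1.0, stretch_max=2.0,
            cfg=SolverConfig(n_increments=4),
        )
        assert res.metadata["u_circ"] == 500.0
        assert res.stretch[-1] == 2.0
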