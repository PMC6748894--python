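"""Design construction, surrogate interpolation, and sensitivity regression."""

import numpy as np
import pytest

from fibernet.sensitivity import (
    denormalize_params,
    design_responses,
    fit_linear,
    fit_quadratic_pruned,
    normalize_params,
)
from fibernet.surrogate import (
    PARAM_NAMES,
    ParameterBounds,
    ReducedScaleConfig,
    SurrogateModel,
    build_design,
    derive_seed,
    run_design,
)

BOUNDS = ParameterBounds()


class TestDesign:
    def test_counts_int_levels(self):
        assert len(build_design(BOUNDS, 3)) == 3**5

    def test_counts_per_axis(self):
        design = build_design(BOUNDS, (6, 5, 5, 6, 8), budget=8000)
        assert len(design) == 7200

    def test_endpoints_are_bounds(self):
        design = build_design(BOUNDS, 2)
        for name in PARAM_NAMES:
            lo, hi = getattr(BOUNDS, name)
            vals = sorted({p[name] for p in design})
            assert vals == [lo, hi]

    def test_budget_guard(self):
        with pytest.raises(ValueError):
            build_design(BOUNDS, 7)  # 7^5 > 10000
        assert len(build_design(BOUNDS, 7, allow_large=True)) == 7**5

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            build_design(BOUNDS, (1, 2, 2, 2, 2))


class TestDerivedSeeds:
    def test_deterministic_and_bounded(self):
        design = build_design(BOUNDS, 2)
        seeds = [derive_seed(p, 42) for p in design]
        assert seeds == [derive_seed(p, 42) for p in design]
        assert all(0 <= s < 2**31 for s in seeds)
        assert len(set(seeds)) == len(seeds)

    def test_master_seed_changes_streams(self):
        p = build_design(BOUNDS, 2)[0]
        assert derive_seed(p, 1) != derive_seed(p, 2)


def multilinear_truth(params, lam):
    """Multilinear in each normalized parameter and in stretch: interpolation
    on any grid must reproduce it exactly everywhere inside the bounds."""
    x = normalize_params(params, BOUNDS)
    return (
        (1.0 + x[0]) * (0.5 + x[1])
        + 2.0 * x[2]
        - x[3] * x[4]
        + (np.asarray(lam) - 1.0) * (1.0 + x[0])
    )


def analytic_surrogate(levels=3, n_stretch=11):
    design = build_design(BOUNDS, levels)
    axes = {
        n: np.unique([p[n] for p in design]) for n in PARAM_NAMES
    }
    stretch = np.linspace(1.0, 2.0, n_stretch)
    shape = tuple(len(axes[n]) for n in PARAM_NAMES) + (n_stretch,)
    stress = np.empty(shape)
    for p in design:
        idx = tuple(int(np.searchsorted(axes[n], p[n])) for n in PARAM_NAMES)
        stress[idx] = multilinear_truth(p, stretch)
    return SurrogateModel(axes=axes, stretch=stretch, stress=stress, metadata={})


class TestSurrogateModel:
    def test_exact_at_grid_nodes(self):
        sm = analytic_surrogate()
        p = {n: sm.axes[n][1] for n in PARAM_NAMES}
        got = sm.evaluate(p, sm.stretch)
        assert np.allclose(got, multilinear_truth(p, sm.stretch), atol=1e-12)

    def test_exact_off_grid_for_multilinear_truth(self):
        sm = analytic_surrogate()
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.uniform(0.05, 0.95, 5)
            p = denormalize_params(x, BOUNDS)
            lam = rng.uniform(1.02, 1.98)
            got = float(sm.evaluate(p, lam)[0])
            assert abs(got - multilinear_truth(p, lam)) < 1e-10

    def test_out_of_grid_refused(self):
        sm = analytic_surrogate()
        p = {n: getattr(BOUNDS, n)[0] for n in PARAM_NAMES}
        p["E_fiber"] = getattr(BOUNDS, "E_fiber")[1] * 1.5
        with pytest.raises(ValueError):
            sm.evaluate(p, 1.5)

    def test_refinement_does_not_change_grid_values(self):
        coarse = analytic_surrogate(levels=2)
        fine = analytic_surrogate(levels=3)
        p = {n: coarse.axes[n][0] for n in PARAM_NAMES}
        assert np.allclose(
            coarse.evaluate(p, coarse.stretch[::2]),
            fine.evaluate(p, coarse.stretch[::2]),
            atol=1e-12,
        )

    def test_hdf5_round_trip(self, tmp_path):
        sm = analytic_surrogate(levels=2)
        sm.metadata = {"master_seed": 3, "note": "round trip"}
        path = tmp_path / "surrogate.h5"
        sm.save(path)
        back = SurrogateModel.load(path)
        assert np.array_equal(back.stress, sm.stress)
        assert np.array_equal(back.stretch, sm.stretch)
        for n in PARAM_NAMES:
            assert np.array_equal(back.axes[n], sm.axes[n])
        assert back.metadata == sm.metadata

    def test_missing_cells_block_interpolation(self):
        sm = analytic_surrogate(levels=2)
        sm.stress[0, 0, 0, 0, 0, 0] = np.nan
        sm._interp = None
        assert sm.missing_cells == 1
        with pytest.raises(ValueError):
            sm.evaluate({n: sm.axes[n][0] for n in PARAM_NAMES}, 1.0)


class TestRunDesign:
    def test_failures_become_nan_and_resume_fills_them(self, monkeypatch):
        import fibernet.surrogate as sur
        from fibernet.mechanics import SolverError

        scale = ReducedScaleConfig(n_stretch=5)
        design = build_design(BOUNDS, 2)
        bad = design[3]
        calls = {"n": 0}

        def fake(params, sc, seed, cfg=None):
            calls["n"] += 1
            if params == bad:
                raise SolverError("synthetic failure")
            return multilinear_truth(params, sc.stretch_axis)

        monkeypatch.setattr(sur, "simulate_parameter_set", fake)
        model = run_design(design, scale=scale, seed=9)
        assert model.missing_cells == scale.n_stretch
        assert len(model.metadata["failures"]) == 1
        first_pass = calls["n"]
        assert first_pass == len(design)

        def fake_ok(params, sc, seed, cfg=None):
            calls["n"] += 1
            return multilinear_truth(params, sc.stretch_axis)

        monkeypatch.setattr(sur, "simulate_parameter_set", fake_ok)
        full = run_design(design, scale=scale, seed=9, existing=model)
        # resume recomputes only the failed cell
        assert calls["n"] == first_pass + 1
        assert full.missing_cells == 0


def synthetic_design_matrix(n=300, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(n, 5))


class TestSensitivityRegression:
    def test_normalize_round_trip(self):
        p = {"E_fiber": 120.0, "K": 1.0, "vf": 0.3, "waviness": 0.7,
             "sigma_deg": 5.0}
        x = normalize_params(p, BOUNDS)
        assert np.all((x >= 0) & (x <= 1))
        back = denormalize_params(x, BOUNDS)
        for n in PARAM_NAMES:
            assert abs(back[n] - p[n]) < 1e-12

    def test_linear_fit_recovers_exact_coefficients(self):
        X = synthetic_design_matrix()
        beta = np.array([0.5, 2.0, -1.0, 0.0, 3.0, -0.5])
        y = beta[0] + X @ beta[1:]
        res = fit_linear(X, y, "slope")
        assert np.allclose(res.coefficients, beta, atol=1e-10)
        assert res.r_squared > 1.0 - 1e-12
        assert res.rmse < 1e-10

    def test_permuted_response_has_no_signal(self):
        rng = np.random.default_rng(3)
        X = synthetic_design_matrix(seed=1)
        y = 2.0 * X[:, 0] + 0.05 * rng.standard_normal(len(X))
        res = fit_linear(X, rng.permutation(y), "null")
        assert res.r_squared < 0.05

    def test_quadratic_prunes_noise_terms(self):
        rng = np.random.default_rng(4)
        X = synthetic_design_matrix(n=500, seed=2)
        y = (
            1.0
            + 2.0 * X[:, 0]
            - 3.0 * X[:, 1] ** 2
            + 4.0 * X[:, 2] * X[:, 3]
            + 0.01 * rng.standard_normal(len(X))
        )
        full, pruned = fit_quadratic_pruned(X, y, "slope")
        assert len(full.terms) == 21
        kept = set(pruned.terms)
        assert {"const", "E_fiber", "K^2", "vf*waviness"} <= kept
        assert "sigma_deg" in pruned.pruned_terms
        # pruned model cannot fit better than the full one
        assert pruned.r_squared <= full.r_squared + 1e-12
        assert pruned.r_squared > 0.999

    def test_fit_preconditions(self):
        X = synthetic_design_matrix(n=5)
        with pytest.raises(ValueError):
            fit_linear(X, np.zeros(5))
        with pytest.raises(ValueError):
            fit_linear(synthetic_design_matrix() + 3.0, np.zeros(300))

    def test_design_responses_shapes(self):
        sm_model = analytic_surrogate(levels=2, n_stretch=21)
        design = build_design(BOUNDS, 2)[:6]
        slopes, recruits = design_responses(sm_model, design)
        assert slopes.shape == (6,) and recruits.shape == (6,)
        assert np.all(np.isfinite(slopes))
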