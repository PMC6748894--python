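"""Inverse identification of network parameters from stress-stretch data.

A real-coded genetic algorithm (tournament selection, blend crossover,
Gaussian mutation, elitism) minimizes a negatively defined R-squared
objective over the gridded surrogate, constrained to the parameter bounds.
Several independent seeded runs are performed and the best optimum returned
together with a per-run table and an identifiability report (spread of each
recovered parameter across runs).

By default only the portion of the curve from the experimental recruitment
stretch onward is fitted: the toe region is dominated by non-collagenous
constituents absent from the network model.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .mechanics import StressStretchCurve
from .metrics import recruitment_stretch
from .surrogate import PARAM_NAMES, ParameterBounds, SurrogateModel, derive_seed

__all__ = [
    "GASettings",
    "IdentificationProblem",
    "IdentifiedParams",
    "objective",
    "identify",
]


def objective(exp: StressStretchCurve, model: StressStretchCurve, weights=None):
    """Negatively defined R-squared: sum(e-m)^2 / sum(e-mean(e))^2 - 1.

    -1 is a perfect fit; 0 is no better than the mean of the data.  The model
    curve is resampled onto the experimental stretch points.
    """
    m = model.resample(exp.stretch).stress
    e = exp.stress
    if weights is None:
        w = np.ones_like(e)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != e.shape or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative with positive mass")
    ebar = float(np.sum(w * e) / np.sum(w))
    denom = float(np.sum(w * (e - ebar) ** 2))
    if denom <= 0:
        raise ValueError("constant experimental curve: objective undefined")
    return float(np.sum(w * (e - m) ** 2) / denom - 1.0)


@dataclasses.dataclass(frozen=True)
class GASettings:
    population: int = 60
    generations: int = 120
    n_runs: int = 8
    tournament: int = 3
    crossover_alpha: float = 0.5    # BLX-alpha blend range extension
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    mutation_sigma: float = 0.1     # in normalized coordinates
    elite: int = 2

    def __post_init__(self):
        if self.population < 4 or self.generations < 1 or self.n_runs < 1:
            raise ValueError("population >= 4, generations/runs >= 1 required")


@dataclasses.dataclass
class IdentificationProblem:
    exp: StressStretchCurve
    surrogate: SurrogateModel
    free: dict                      # name -> (lo, hi), subset of PARAM_NAMES
    fixed: dict                     # name -> value for the rest
    settings: GASettings = dataclasses.field(default_factory=GASettings)
    seed: int = 0
    from_recruitment: bool = True   # fit only lambda >= recruitment stretch

    def __post_init__(self):
        names = set(self.free) | set(self.fixed)
        if names != set(PARAM_NAMES):
            raise ValueError(
                f"free + fixed must cover exactly {PARAM_NAMES}, got {sorted(names)}"
            )
        table = ParameterBounds()
        for name, (lo, hi) in self.free.items():
            tlo, thi = getattr(table, name)
            if lo < tlo - 1e-9 or hi > thi + 1e-9 or lo >= hi:
                raise ValueError(f"free bounds for {name} outside the table range")


@dataclasses.dataclass
class IdentifiedParams:
    values: dict                   # all five parameters
    objective: float
    r_squared: float
    n_runs: int
    per_run: list                  # [{"params":..., "objective":...}]
    identifiability: dict          # name -> spread across runs / bound range
    history: list                  # best objective per generation (best run)


def _fit_weights(problem: IdentificationProblem):
    if not problem.from_recruitment:
        return None
    lam_r = recruitment_stretch(problem.exp)
    if not np.isfinite(lam_r):
        return None
    return (problem.exp.stretch >= lam_r).astype(float)


def identify(problem: IdentificationProblem) -> IdentifiedParams:
    """Best-of-N-runs GA minimization of the objective over the surrogate."""
    st = problem.settings
    free_names = [n for n in PARAM_NAMES if n in problem.free]
    lo = np.array([problem.free[n][0] for n in free_names])
    hi = np.array([problem.free[n][1] for n in free_names])
    d = len(free_names)
    if d == 0:
        raise ValueError("no free parameters")
    weights = _fit_weights(problem)
    exp = problem.exp
    lam = exp.stretch
    cache: dict = {}

    def evaluate(xn):
        key = tuple(np.round(xn, 12))
        if key in cache:
            return cache[key]
        params = dict(problem.fixed)
        vals = lo + xn * (hi - lo)
        params.update(dict(zip(free_names, vals)))
        stress = problem.surrogate.evaluate(params, lam)
        val = objective(exp, StressStretchCurve(lam, stress), weights)
        cache[key] = val
        return val

    def ga_run(run_idx):
        rng = np.random.default_rng(
            derive_seed({**problem.fixed, **{n: problem.free[n][0] for n in free_names}},
                        problem.seed + 1009 * run_idx)
        )
        pop = rng.random((st.population, d))
        fit = np.array([evaluate(x) for x in pop])
        history = [float(fit.min())]
        for _gen in range(st.generations):
            order = np.argsort(fit)
            elite = pop[order[: st.elite]].copy()
            children = list(elite)
            while len(children) < st.population:
                # tournament selection of two parents
                def pick():
                    idx = rng.integers(0, st.population, st.tournament)
                    return pop[idx[np.argmin(fit[idx])]]

                p1, p2 = pick(), pick()
                if rng.random() < st.crossover_rate:
                    span = np.abs(p1 - p2)
                    lo_c = np.minimum(p1, p2) - st.crossover_alpha * span
                    hi_c = np.maximum(p1, p2) + st.crossover_alpha * span
                    child = lo_c + rng.random(d) * (hi_c - lo_c)
                else:
                    child = p1.copy()
                mut = rng.random(d) < st.mutation_rate
                child = child + mut * rng.normal(0.0, st.mutation_sigma, d)
                children.append(np.clip(child, 0.0, 1.0))
            pop = np.asarray(children[: st.population])
            fit = np.array([evaluate(x) for x in pop])
            history.append(float(fit.min()))
        best = int(np.argmin(fit))
        return pop[best], float(fit[best]), history

    per_run = []
    best_x, best_val, best_hist = None, np.inf, None
    for run_idx in range(st.n_runs):
        x, val, hist = ga_run(run_idx)
        params = dict(problem.fixed)
        params.update(dict(zip(free_names, lo + x * (hi - lo))))
        per_run.append({"params": params, "objective": val})
        if val < best_val:
            best_x, best_val, best_hist = x, val, hist

    values = dict(problem.fixed)
    values.update(dict(zip(free_names, lo + best_x * (hi - lo))))
    spread = {}
    for j, name in enumerate(free_names):
        vals = np.array([r["params"][name] for r in per_run])
        spread[name] = float((vals.max() - vals.min()) / (hi[j] - lo[j]))
    return IdentifiedParams(
        values=values,
        objective=best_val,
        r_squared=-best_val,
        n_runs=st.n_runs,
        per_run=per_run,
        identifiability=spread,
        history=best_hist,
    )
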