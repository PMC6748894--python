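"""Linear and quadratic sensitivity regression of surrogate responses.

Responses (final slope, recruitment stretch) from a design of experiments are
regressed on the five parameters normalized to [0, 1] over their bounds.
The linear model uses 5 linear terms plus a constant; the quadratic model
uses the full quadratic basis (5 linear, 5 squares, 10 pairwise interactions,
1 constant) with a single pruning pass that removes terms whose p-value
exceeds 0.05 and refits.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import statsmodels.api as sm

from .surrogate import PARAM_NAMES, ParameterBounds

__all__ = [
    "SensitivityResult",
    "normalize_params",
    "denormalize_params",
    "fit_linear",
    "fit_quadratic_pruned",
    "design_responses",
]


@dataclasses.dataclass
class SensitivityResult:
    response: str
    terms: list            # term names, constant first
    coefficients: np.ndarray
    p_values: np.ndarray
    rmse: float
    r_squared: float
    pruned_terms: list     # names removed in the pruning pass (p > 0.05)

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def as_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": list(self.terms),
            "coefficients": [float(c) for c in self.coefficients],
            "p_values": [float(p) for p in self.p_values],
            "rmse": self.rmse,
            "r_squared": self.r_squared,
            "pruned_terms": list(self.pruned_terms),
        }


def _design_matrix(design, bounds: ParameterBounds) -> np.ndarray:
    X = np.empty((len(design), len(PARAM_NAMES)))
    for j, name in enumerate(PARAM_NAMES):
        lo, hi = getattr(bounds, name)
        vals = np.asarray([p[name] for p in design], dtype=float)
        if np.any(vals < lo - 1e-9) or np.any(vals > hi + 1e-9):
            raise ValueError(f"{name} values outside bounds [{lo}, {hi}]")
        X[:, j] = (vals - lo) / (hi - lo)
    return X


def normalize_params(design, bounds: ParameterBounds) -> np.ndarray:
    """Map each parameter to [0, 1]: 0 at the lower, 1 at the upper bound."""
    if isinstance(design, dict):
        return _design_matrix([design], bounds)[0]
    return _design_matrix(list(design), bounds)


def denormalize_params(x, bounds: ParameterBounds) -> dict:
    """Inverse of ``normalize_params`` for a single normalized vector."""
    x = np.asarray(x, dtype=float)
    out = {}
    for j, name in enumerate(PARAM_NAMES):
        lo, hi = getattr(bounds, name)
        out[name] = float(lo + x[j] * (hi - lo))
    return out


def _ols(terms, A, y, response):
    model = sm.OLS(y, A)
    fit = model.fit()
    resid = y - fit.fittedvalues
    return fit, SensitivityResult(
        response=response,
        terms=list(terms),
        coefficients=np.asarray(fit.params, dtype=float),
        p_values=np.asarray(fit.pvalues, dtype=float),
        rmse=float(np.sqrt(np.mean(resid**2))),
        r_squared=float(fit.rsquared),
        pruned_terms=[],
    )


def fit_linear(X, y, response: str = "response") -> SensitivityResult:
    """OLS with the 5 linear terms + constant on normalized predictors.

    Rows with a non-finite response (e.g. curves where no recruitment is
    detectable) are dropped before fitting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"X must be (n, {len(PARAM_NAMES)}) normalized design")
    keep = np.isfinite(y)
    X, y = X[keep], y[keep]
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more rows than regression terms")
    if np.any(X < -1e-9) or np.any(X > 1 + 1e-9):
        raise ValueError("predictors must be normalized to [0, 1]")
    A = np.column_stack([np.ones(len(X)), X])
    terms = ["const"] + list(PARAM_NAMES)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient design")
    _, result = _ols(terms, A, y, response)
    return result


def _quadratic_basis(X):
    cols = [np.ones(len(X))]
    names = ["const"]
    for j, name in enumerate(PARAM_NAMES):
        cols.append(X[:, j])
        names.append(name)
    for j, name in enumerate(PARAM_NAMES):
        cols.append(X[:, j] ** 2)
        names.append(f"{name}^2")
    for (i, ni), (j, nj) in itertools.combinations(enumerate(PARAM_NAMES), 2):
        cols.append(X[:, i] * X[:, j])
        names.append(f"{ni}*{nj}")
    return np.column_stack(cols), names


def fit_quadratic_pruned(
    X, y, response: str = "response", alpha: float = 0.05
):
    """Full quadratic fit, then one pruning pass removing p > alpha terms.

    Returns (full fit, pruned fit); the constant is never pruned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    finite = np.isfinite(y)
    X, y = X[finite], y[finite]
    A, names = _quadratic_basis(X)
    if X.shape[0] <= len(names):
        raise ValueError("need more rows than quadratic terms")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient quadratic design")
    _, full = _ols(names, A, y, response)
    keep = [
        i
        for i in range(len(names))
        if names[i] == "const" or full.p_values[i] <= alpha
    ]
    pruned_names = [names[i] for i in range(len(names)) if i not in keep]
    if len(keep) == 1:
        import warnings

        warnings.warn("all terms pruned; returning the constant model")
    _, pruned = _ols(
        [names[i] for i in keep], A[:, keep], y, response
    )
    pruned.pruned_terms = pruned_names
    return full, pruned


def design_responses(surrogate, design, smoothing_window: int = 5):
    """Final slope and recruitment stretch of every design point's curve."""
    from .metrics import final_slope, recruitment_stretch

    slopes = np.empty(len(design))
    recruits = np.empty(len(design))
    for i, params in enumerate(design):
        curve = surrogate.curve(params)
        slopes[i] = final_slope(curve)
        recruits[i] = recruitment_stretch(curve, window=smoothing_window)
    return slopes, recruits
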