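"""Probability models for collagen fiber orientation and waviness.

Fiber orientation in the axial-circumferential plane is modelled as a
two-family, pi-periodic von Mises mixture

    f(theta) = p * exp(k1*cos 2(theta - mu1)) / (pi * I0(k1))
             + (1 - p) * exp(k2*cos 2(theta - mu2)) / (pi * I0(k2))

with concentration parameters k1, k2 > 0, family means mu1, mu2 and weight
0 < p < 1.  The doubled angle makes the density pi-periodic, matching the
head/tail symmetry of a fiber.  Fiber waviness W = ls/lc (end-to-end over
contour length, in (0, 1]) follows a beta distribution.

Sampling is by inverse transform on a tabulated CDF; fitting is maximum
likelihood with multiple restarts.  The dispersion relation
sigma^2 = 1 - I1(k)/I0(k) converts between the concentration parameter and
the circular standard deviation of the doubled angle.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "OrientationMixture",
    "WavinessDist",
    "AngleSample",
    "mixture_pdf",
    "sample_orientations",
    "sample_waviness",
    "fit_mixture",
    "fit_beta",
    "k_from_sigma",
    "sigma_from_k",
    "k_from_sigma_deg",
    "sigma_deg_from_k",
]

_TWO_PI = 2.0 * math.pi


def _wrap_pi(theta):
    """Wrap angles to the fundamental domain [0, pi)."""
    return np.mod(theta, math.pi)


@dataclasses.dataclass(frozen=True)
class OrientationMixture:
    """Two-family pi-periodic von Mises mixture.

    Angles are stored in radians with family means in [0, pi); ``p`` is the
    weight of family 1.
    """

    mu1: float
    mu2: float
    k1: float
    k2: float
    p: float

    def __post_init__(self):
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("concentration parameters must be positive")
        if not (0.0 < self.p < 1.0):
            raise ValueError("mixture weight p must lie in (0, 1)")
        object.__setattr__(self, "mu1", float(_wrap_pi(self.mu1)))
        object.__setattr__(self, "mu2", float(_wrap_pi(self.mu2)))

    @classmethod
    def from_degrees(cls, mu1_deg, mu2_deg, k1, k2, p):
        return cls(math.radians(mu1_deg), math.radians(mu2_deg), k1, k2, p)

    def pdf(self, theta):
        return mixture_pdf(theta, self)

    def cdf_table(self, resolution: int = 4096):
        """Tabulated CDF over [0, pi] for inverse-transform sampling."""
        grid = np.linspace(0.0, math.pi, resolution + 1)
        dens = self.pdf(grid)
        cdf = np.concatenate(
            [[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(grid))]
        )
        cdf /= cdf[-1]
        return grid, cdf

    def family_means_deg(self):
        """Family means in degrees mapped to (-90, 90]."""
        out = []
        for mu in (self.mu1, self.mu2):
            deg = math.degrees(mu) % 180.0
            if deg > 90.0:
                deg -= 180.0
            out.append(deg)
        return tuple(out)

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class WavinessDist:
    """Beta distribution for fiber waviness W = ls/lc on (0, 1]."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("beta shape parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def var(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    def pdf(self, w):
        return stats.beta.pdf(w, self.alpha, self.beta)

    @classmethod
    def from_mean(cls, mean: float, total: float = 21.99) -> "WavinessDist":
        """One-parameter family through a target mean at fixed alpha+beta.

        ``total`` defaults to the alpha+beta of the distribution fitted to
        traced adventitial fibers (15.78 + 6.21).
        """
        if not 0.0 < mean < 1.0:
            raise ValueError("mean waviness must lie in (0, 1)")
        return cls(mean * total, (1.0 - mean) * total)


@dataclasses.dataclass(frozen=True)
class AngleSample:
    """A reproducible draw of fiber angles in [0, pi)."""

    values: np.ndarray
    seed: int

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if np.any((vals < 0) | (vals >= math.pi)):
            raise ValueError("angles must lie in [0, pi)")
        object.__setattr__(self, "values", vals)


def _vm_component(theta, mu, k):
    # exp(k cos 2(t-mu)) / (pi I0(k)), computed with the exponentially
    # scaled Bessel function for stability at large k.
    return np.exp(k * (np.cos(2.0 * (theta - mu)) - 1.0)) / (
        math.pi * special.i0e(k)
    )


def mixture_pdf(theta, mix: OrientationMixture):
    """Density (1/radian) of the orientation mixture; pi-periodic in theta."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    return mix.p * _vm_component(theta, mix.mu1, mix.k1) + (
        1.0 - mix.p
    ) * _vm_component(theta, mix.mu2, mix.k2)


def sample_orientations(
    mix: OrientationMixture, n: int, seed: int, resolution: int = 4096
) -> AngleSample:
    """Inverse-transform sample of n fiber angles from the mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    grid, cdf = mix.cdf_table(resolution)
    u = rng.random(n)
    vals = np.interp(u, cdf, grid)
    # the top grid point maps to pi itself; fold back into [0, pi)
    return AngleSample(_wrap_pi(vals), seed)


def sample_waviness(dist: WavinessDist, n: int, seed: int) -> np.ndarray:
    """Sample n waviness values in (0, 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    w = stats.beta.rvs(dist.alpha, dist.beta, size=n, random_state=rng)
    return np.clip(w, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)


def _mixture_nll(params, theta):
    mu1, mu2, logk1, logk2, logit_p = params
    # clip so wandering optimizer steps cannot overflow exp(); k = e^20 is
    # already far sharper than any physical orientation data
    k1 = math.exp(min(max(logk1, -20.0), 20.0))
    k2 = math.exp(min(max(logk2, -20.0), 20.0))
    p = 1.0 / (1.0 + math.exp(-min(max(logit_p, -500.0), 500.0)))
    dens = p * _vm_component(theta, mu1, k1) + (1.0 - p) * _vm_component(
        theta, mu2, k2
    )
    return -np.mean(np.log(np.maximum(dens, 1e-300)))


def fit_mixture(
    angles: AngleSample, n_restarts: int = 8, seed: int = 0
) -> tuple[OrientationMixture, float]:
    """Maximum-likelihood fit of the five mixture parameters.

    Runs ``n_restarts`` local optimizations from randomized starting points
    and returns the best solution with the canonical labelling mu1 < mu2
    (weights relabelled accordingly), together with the total log-likelihood.
    """
    theta = np.asarray(getattr(angles, "values", angles), dtype=float)
    if theta.size < 100:
        raise ValueError("need at least 100 angles for a stable fit")
    rng = np.random.default_rng(seed)

    # moment-flavoured initial guess: modes of a coarse histogram
    hist, edges = np.histogram(theta, bins=36, range=(0.0, math.pi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    order = np.argsort(hist)[::-1]
    mu_a = centers[order[0]]
    # second mode at least 30 degrees away from the first
    mu_b = mu_a + math.pi / 2.0
    for idx in order[1:]:
        sep = abs((centers[idx] - mu_a + math.pi / 2.0) % math.pi - math.pi / 2.0)
        if sep > math.radians(30.0):
            mu_b = centers[idx]
            break

    # restarts explore on a subsample; the best candidates are polished on
    # the full data (the likelihood surface is smooth, only multi-modal)
    sub = theta if theta.size <= 20000 else rng.choice(theta, 20000, replace=False)
    candidates = []
    for restart in range(n_restarts):
        if restart == 0:
            x0 = np.array([mu_a, mu_b, math.log(8.0), math.log(8.0), 0.0])
        else:
            x0 = np.array(
                [
                    rng.uniform(0.0, math.pi),
                    rng.uniform(0.0, math.pi),
                    math.log(rng.uniform(1.0, 30.0)),
                    math.log(rng.uniform(1.0, 30.0)),
                    rng.normal(scale=1.0),
                ]
            )
        res = optimize.minimize(
            _mixture_nll,
            x0,
            args=(sub,),
            method="Nelder-Mead",
            options={"maxiter": 3000, "xatol": 1e-6, "fatol": 1e-9},
        )
        if np.isfinite(res.fun):
            candidates.append(res)
    if not candidates:
        raise RuntimeError("mixture fit failed to converge from all restarts")
    candidates.sort(key=lambda r: r.fun)
    best = None
    for cand in candidates[:2]:
        res = optimize.minimize(
            _mixture_nll,
            cand.x,
            args=(theta,),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("mixture fit failed to converge from all restarts")

    mu1, mu2, logk1, logk2, logit_p = best.x
    k1 = math.exp(min(max(logk1, -20.0), 20.0))
    k2 = math.exp(min(max(logk2, -20.0), 20.0))
    p = 1.0 / (1.0 + math.exp(-min(max(logit_p, -500.0), 500.0)))
    mu1, mu2 = float(_wrap_pi(mu1)), float(_wrap_pi(mu2))
    if mu1 > mu2:
        mu1, mu2, k1, k2, p = mu2, mu1, k2, k1, 1.0 - p
    mix = OrientationMixture(mu1, mu2, k1, k2, min(max(p, 1e-9), 1 - 1e-9))
    loglik = -best.fun * theta.size
    return mix, loglik


def fit_beta(w) -> WavinessDist:
    """Maximum-likelihood beta fit of waviness values in (0, 1)."""
    w = np.asarray(w, dtype=float)
    if np.any((w <= 0.0) | (w >= 1.0)):
        raise ValueError("waviness values must lie strictly inside (0, 1)")
    alpha, beta, _, _ = stats.beta.fit(w, floc=0.0, fscale=1.0)
    return WavinessDist(alpha, beta)


def _dispersion(k):
    """sigma^2 = 1 - I1(k)/I0(k); strictly decreasing in k."""
    return 1.0 - special.i1e(k) / special.i0e(k)


def sigma_from_k(k: float) -> float:
    """Circular std (radians, doubled-angle scale) from concentration k."""
    if k <= 0:
        raise ValueError("k must be positive")
    return math.sqrt(_dispersion(k))


def k_from_sigma(sigma: float) -> float:
    """Concentration k from the circular std of the doubled angle (radians).

    Solves sigma^2 = 1 - I1(k)/I0(k) by bracketed root finding.
    """
    if not 0.0 < sigma < 1.0:
        raise ValueError("sigma must lie in (0, 1) radians")
    target = sigma * sigma
    lo, hi = 1e-10, 1e10
    if not (_dispersion(hi) < target < _dispersion(lo)):
        raise ValueError("sigma outside the feasible dispersion range")
    return optimize.brentq(
        lambda k: _dispersion(k) - target, lo, hi, xtol=1e-14, rtol=1e-14
    )


def k_from_sigma_deg(sigma_deg: float, convention: str = "doubled") -> float:
    """Concentration from a dispersion quoted in degrees.

    ``convention='doubled'`` (default) treats the quoted value as half the
    circular std of the doubled angle, matching the printed dispersion
    formula; ``'native'`` treats it as the std of the angle itself.
    """
    if convention == "doubled":
        sigma = math.radians(2.0 * sigma_deg)
    elif convention == "native":
        sigma = math.radians(sigma_deg)
    else:
        raise ValueError(f"unknown sigma convention: {convention!r}")
    return k_from_sigma(sigma)


def sigma_deg_from_k(k: float, convention: str = "doubled") -> float:
    sigma = sigma_from_k(k)
    if convention == "doubled":
        return math.degrees(sigma) / 2.0
    if convention == "native":
        return math.degrees(sigma)
    raise ValueError(f"unknown sigma convention: {convention!r}")
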