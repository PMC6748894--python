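"""Micro- and macro-scale metrics extracted from network simulations.

Macroscopic descriptors of the stress-stretch response (final slope,
recruitment stretch), microscopic descriptors of the deforming network
(fiber reorientation, straightening/waviness, non-affinity of the
displacement field), fiber-level strain/stress states at a target wall
stress, and a rupture probability index built on them.

Conventions
-----------
* The fiber angle theta is measured from the loading (x) axis; global fiber
  angles are computed from the deformed end-to-end vector and reported on
  (-90, 90] degrees.  Percentage reorientation uses the folded angle
  |theta| in [0, 90]: 100 * |theta_0 - theta_t| / theta_0 per fiber.
* Non-affinity NA (in %) is the node-average squared deviation of the local
  strain/rotation vector E = (eps11, eps22, eps12, omega12), obtained by a
  least-squares affine fit over neighbors within a probe radius, from its
  affine counterpart computed with the applied axial stretch and the
  realized (pivot) transverse stretch; the result is scaled by 100.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .distributions import OrientationMixture, fit_mixture
from .mechanics import SimulationResult, StressStretchCurve

__all__ = [
    "MetricError",
    "MetricReport",
    "OrientationEvolution",
    "RuptureProbability",
    "StrainState",
    "final_slope",
    "recruitment_stretch",
    "orientation_evolution",
    "average_waviness",
    "non_affinity",
    "state_at_stress",
    "rupture_probability",
    "metric_report",
]


class MetricError(ValueError):
    """A metric precondition is violated."""


# --------------------------------------------------------------------------
# macroscopic curve metrics
# --------------------------------------------------------------------------


def final_slope(curve: StressStretchCurve) -> float:
    """Least-squares slope (MPa) over the final 10% of the stretch range."""
    lam = curve.stretch
    sig = curve.stress
    lam_max = float(lam[-1])
    cut = lam_max - 0.1 * (lam_max - 1.0)
    mask = lam >= cut - 1e-12
    if int(np.sum(mask)) < 3:
        raise MetricError(
            "final slope needs at least 3 points in the last 10% of stretch"
        )
    A = np.stack([lam[mask], np.ones(int(np.sum(mask)))], axis=1)
    coef, *_ = np.linalg.lstsq(A, sig[mask], rcond=None)
    return float(coef[0])


def recruitment_stretch(curve: StressStretchCurve, window: int = 5) -> float:
    """Stretch of the fastest slope change (collagen recruitment point).

    The discrete second derivative of stress with respect to stretch is
    smoothed by a centered moving average of the given window and its argmax
    returned.  A curvature-free (linear) curve returns ``nan`` with a
    warning: no recruitment is detectable.
    """
    lam = curve.stretch
    sig = curve.stress
    if len(lam) < 7:
        raise MetricError("recruitment detection needs at least 7 points")
    if np.any(np.diff(lam) <= 0):
        raise MetricError("stretch must be strictly increasing")
    d1 = np.gradient(sig, lam)
    d2 = np.gradient(d1, lam)
    w = max(1, int(window))
    kernel = np.ones(w) / w
    d2s = np.convolve(d2, kernel, mode="same")
    scale = max(abs(sig[-1] - sig[0]), 1e-30) / max(lam[-1] - lam[0], 1e-30) ** 2
    if np.max(d2s) <= 1e-8 * scale:
        warnings.warn("no recruitment detected: curve has no upward curvature")
        return float("nan")
    return float(lam[int(np.argmax(d2s))])


# --------------------------------------------------------------------------
# orientation / reorientation
# --------------------------------------------------------------------------


@dataclasses.dataclass
class OrientationEvolution:
    """Per-increment fiber orientations and percentage reorientation."""

    stretch: np.ndarray              # (T,)
    angles_deg: np.ndarray           # (T, F) signed angle on (-90, 90]
    reorientation_percent: np.ndarray  # (T, F)
    mean_reorientation: np.ndarray   # (T,)

    def refit_final(self, n_restarts: int = 8, seed: int = 0):
        """Refit the two-family mixture to the final fiber angles."""
        ang = np.deg2rad(self.angles_deg[-1]) % math.pi
        mix, _ = fit_mixture(ang, n_restarts=n_restarts, seed=seed)
        return mix


def _fiber_end_indices(net):
    ends = np.empty((net.n_fibers, 2), dtype=np.int64)
    for fid in range(net.n_fibers):
        idx = net.fiber_node_indices(fid)
        ends[fid] = idx[0], idx[-1]
    return ends


def orientation_evolution(result: SimulationResult) -> OrientationEvolution:
    """Track each fiber's global (end-to-end) angle through the loading."""
    net = result.network
    ends = _fiber_end_indices(net)
    X = net.nodes
    T = result.displacements.shape[0]
    angles = np.empty((T, net.n_fibers))
    for t in range(T):
        x = X + result.displacements[t]
        d = x[ends[:, 1]] - x[ends[:, 0]]
        a = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        a = (a + 90.0) % 180.0 - 90.0          # fold to (-90, 90]
        a[a == -90.0] = 90.0
        angles[t] = a
    folded = np.abs(angles)
    theta0 = folded[0]
    safe = theta0 > 1e-9
    reo = np.zeros_like(folded)
    reo[:, safe] = np.abs(theta0[safe] - folded[:, safe]) / theta0[safe] * 100.0
    return OrientationEvolution(
        stretch=result.stretch,
        angles_deg=angles,
        reorientation_percent=reo,
        mean_reorientation=reo.mean(axis=1),
    )


def affine_angle_deg(theta0_deg, lam: float, lam_t: float):
    """Affine rotation of a line element: tan(theta) scales by lam_t/lam."""
    th0 = np.deg2rad(np.asarray(theta0_deg, dtype=float))
    return np.degrees(np.arctan2(np.sin(th0) * lam_t, np.cos(th0) * lam))


# --------------------------------------------------------------------------
# waviness / straightening
# --------------------------------------------------------------------------


def average_waviness(result: SimulationResult) -> np.ndarray:
    """Network-average fiber waviness (chord/contour) per increment."""
    net = result.network
    X = net.nodes
    T = result.displacements.shape[0]
    fiber_nodes = [net.fiber_node_indices(f) for f in range(net.n_fibers)]
    out = np.empty(T)
    for t in range(T):
        x = X + result.displacements[t]
        w = np.empty(net.n_fibers)
        for f, idx in enumerate(fiber_nodes):
            v = x[idx]
            lc = float(np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1)))
            ls = float(np.linalg.norm(v[-1] - v[0]))
            w[f] = min(ls / lc, 1.0)
        out[t] = w.mean()
    return out


# --------------------------------------------------------------------------
# non-affinity
# --------------------------------------------------------------------------


def _local_fit_operators(X2, r):
    """Per-node least-squares operators for the local displacement gradient.

    Returns (node indices used, list of neighbor-index arrays, list of
    pseudo-inverse operators A with G^T = A @ dU) and the excluded count.
    """
    tree = cKDTree(X2)
    pairs = tree.query_ball_tree(tree, r)
    used, nbrs, ops = [], [], []
    excluded = 0
    for i, group in enumerate(pairs):
        g = [j for j in group if j != i]
        if len(g) < 3:
            excluded += 1
            continue
        dX = X2[g] - X2[i]
        M = dX.T @ dX
        if np.linalg.cond(M) > 1e8:
            excluded += 1
            continue
        used.append(i)
        nbrs.append(np.asarray(g, dtype=np.int64))
        ops.append(np.linalg.solve(M, dX.T))
    return used, nbrs, ops, excluded


def non_affinity(
    result: SimulationResult,
    r: float | None = None,
) -> np.ndarray:
    """NA(lambda) history in % (mean squared deviation from affine, x100).

    The probe radius ``r`` defaults to the mean segment length.  Nodes with
    fewer than 3 neighbors inside the probe radius (or a rank-deficient
    neighborhood) are excluded; the exclusion count is recorded on the
    result metadata as ``na_excluded_nodes``.
    """
    net = result.network
    X2 = net.nodes[:, :2]
    if r is None:
        r = float(np.mean(result.network.segment_lengths))
    if r <= 0:
        raise MetricError("probe radius must be positive")
    used, nbrs, ops, excluded = _local_fit_operators(X2, r)
    result.metadata["na_excluded_nodes"] = excluded
    if not used:
        raise MetricError("no node has enough neighbors within the probe radius")
    T = result.displacements.shape[0]
    lam = result.stretch
    lam_t = result.transverse_stretch
    na = np.empty(T)
    U_all = result.displacements[:, :, :2]
    for t in range(T):
        U = U_all[t]
        E_aff = np.array([lam[t] - 1.0, lam_t[t] - 1.0, 0.0, 0.0])
        dev2 = 0.0
        for i, g, A in zip(used, nbrs, ops):
            Gt = A @ (U[g] - U[i])            # (2, 2) = G^T
            e11 = Gt[0, 0]
            e22 = Gt[1, 1]
            e12 = 0.5 * (Gt[0, 1] + Gt[1, 0])
            w12 = 0.5 * (Gt[1, 0] - Gt[0, 1])  # of G (= -asym of G^T row view)
            E = np.array([e11, e22, e12, w12])
            d = E - E_aff
            dev2 += float(d @ d)
        na[t] = dev2 / len(used) * 100.0
    return na


def local_strain_state(X2, U2, node: int, neighbors) -> np.ndarray:
    """E = (eps11, eps22, eps12, omega12) of the LSQ-fitted local affine map."""
    g = np.asarray(neighbors, dtype=np.int64)
    if len(g) < 3:
        raise MetricError("need at least 3 neighbors")
    dX = X2[g] - X2[node]
    M = dX.T @ dX
    Gt = np.linalg.solve(M, dX.T) @ (U2[g] - U2[node])
    return np.array(
        [
            Gt[0, 0],
            Gt[1, 1],
            0.5 * (Gt[0, 1] + Gt[1, 0]),
            0.5 * (Gt[1, 0] - Gt[0, 1]),
        ]
    )


# --------------------------------------------------------------------------
# fiber state at a target stress / rupture
# --------------------------------------------------------------------------


@dataclasses.dataclass
class StrainState:
    """Per-segment axial strain/stress at an interpolated macro stress."""

    sigma_target: float
    stretch: float
    seg_strain: np.ndarray
    seg_stress: np.ndarray
    strain_hist: tuple      # (counts, bin edges)
    stress_hist: tuple


def state_at_stress(
    result: SimulationResult,
    sigma_target: float,
    bins: int = 50,
) -> StrainState:
    """Interpolate the per-segment state to the target macro PK1 stress."""
    pk1 = result.pk1
    if sigma_target < 0:
        raise MetricError("target stress must be non-negative")
    if sigma_target > pk1[-1] + 1e-12:
        raise MetricError(
            f"target stress {sigma_target} MPa exceeds the simulated maximum "
            f"{pk1[-1]:.4g} MPa; extend the simulation"
        )
    if sigma_target <= pk1[0]:
        i0, i1, w = 0, 0, 0.0
    else:
        i1 = int(np.searchsorted(pk1, sigma_target))
        i1 = min(max(i1, 1), len(pk1) - 1)
        i0 = i1 - 1
        denom = pk1[i1] - pk1[i0]
        w = 0.0 if denom <= 0 else (sigma_target - pk1[i0]) / denom
    eps = (1.0 - w) * result.seg_strain[i0] + w * result.seg_strain[i1]
    sig = (1.0 - w) * result.seg_stress[i0] + w * result.seg_stress[i1]
    lam = (1.0 - w) * result.stretch[i0] + w * result.stretch[i1]
    return StrainState(
        sigma_target=float(sigma_target),
        stretch=float(lam),
        seg_strain=eps,
        seg_stress=sig,
        strain_hist=np.histogram(eps, bins=bins),
        stress_hist=np.histogram(sig, bins=bins),
    )


@dataclasses.dataclass
class RuptureProbability:
    probability: float       # from the fitted density (or empirical fallback)
    empirical: float         # fraction of fibers at/over the threshold
    fitted: bool
    params: tuple | None     # (a, b, loc, scale) of the beta fit, if any


def rupture_probability(
    strains,
    threshold: float = 0.10,
    fit: str | None = "beta",
) -> RuptureProbability:
    """Probability that fiber strain reaches the rupture threshold.

    A beta density is fitted on the rescaled strain support and its upper
    tail at the threshold returned, alongside the raw empirical fraction.
    Degenerate (constant) strain sets skip the fit.
    """
    x = np.asarray(strains, dtype=float).ravel()
    if len(x) == 0:
        raise MetricError("empty strain sample")
    if threshold < 0:
        raise MetricError("threshold must be non-negative")
    empirical = float(np.mean(x >= threshold))
    if threshold == 0.0:
        return RuptureProbability(1.0, 1.0, False, None)
    lo, hi = float(np.min(x)), float(np.max(x))
    if fit is None or hi - lo <= 1e-12 * max(abs(hi), 1.0):
        return RuptureProbability(empirical, empirical, False, None)
    if fit != "beta":
        raise MetricError(f"unknown density '{fit}'")
    span = hi - lo
    # anchor the lower support just below the sample minimum; the upper
    # support (scale) is fitted so the density can extend past max(x)
    loc = lo - 1e-6 * span
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a, b, loc_f, scale_f = stats.beta.fit(x, floc=loc)
    zt = (threshold - loc_f) / scale_f
    if zt <= 0.0:
        p = 1.0
    elif zt >= 1.0:
        p = 0.0
    else:
        p = float(stats.beta.sf(zt, a, b))
    return RuptureProbability(p, empirical, True, (a, b, loc_f, scale_f))


# --------------------------------------------------------------------------
# aggregate report
# --------------------------------------------------------------------------


@dataclasses.dataclass
class MetricReport:
    final_slope: float
    recruitment_stretch: float
    mean_reorientation_percent: float
    reorientation_percent: np.ndarray   # per fiber, final increment
    average_waviness: np.ndarray        # history
    non_affinity: np.ndarray            # history (%)
    strain_state: StrainState | None
    rupture: RuptureProbability | None

    def as_dict(self) -> dict:
        d = {
            "final_slope_MPa": self.final_slope,
            "recruitment_stretch": self.recruitment_stretch,
            "mean_reorientation_percent": float(self.mean_reorientation_percent),
            "average_waviness_final": float(self.average_waviness[-1]),
            "non_affinity_final_percent": float(self.non_affinity[-1]),
        }
        if self.strain_state is not None:
            d["stress_target_MPa"] = self.strain_state.sigma_target
            d["stretch_at_target"] = self.strain_state.stretch
        if self.rupture is not None:
            d["rupture_probability"] = self.rupture.probability
            d["rupture_empirical_fraction"] = self.rupture.empirical
        return d


def metric_report(
    result: SimulationResult,
    sigma_target: float | None = 1.0,
    rupture_threshold: float = 0.10,
    probe_radius: float | None = None,
) -> MetricReport:
    """Compute the full metric suite for one simulation."""
    curve = StressStretchCurve(result.stretch, result.pk1)
    evo = orientation_evolution(result)
    state = None
    rupture = None
    if sigma_target is not None and sigma_target <= result.pk1[-1]:
        state = state_at_stress(result, sigma_target)
        rupture = rupture_probability(state.seg_strain, rupture_threshold)
    return MetricReport(
        final_slope=final_slope(curve),
        recruitment_stretch=recruitment_stretch(curve),
        mean_reorientation_percent=evo.mean_reorientation[-1],
        reorientation_percent=evo.reorientation_percent[-1],
        average_waviness=average_waviness(result),
        non_affinity=non_affinity(result, probe_radius),
        strain_state=state,
        rupture=rupture,
    )
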