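"""Random-walk reconstruction of a discrete 3-D collagen fiber network.

Each fiber is a worm-like chain of straight segments of length ``l_seg``
zigzagging about a global in-plane orientation theta: consecutive segments
alternate at +/- theta_rel about theta, with cos(theta_rel) = W so the
chord-to-contour ratio of the chain equals the sampled waviness.  Fibers
propagate in the axial-circumferential plane at the depth of their seed
point (negligible polar angle) until both ends reach the box boundary, so
no fiber dangles inside the volume.  Fibers are added until the target
collagen volume fraction is reached.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .distributions import OrientationMixture, WavinessDist

__all__ = [
    "BoxDomain",
    "FiberPath",
    "FiberNetwork",
    "generate_network",
    "volume_fraction",
    "fiber_waviness",
]


@dataclasses.dataclass(frozen=True)
class BoxDomain:
    """Rectangular simulation volume (micrometres); loading along ``axis``."""

    Lx: float = 500.0
    Ly: float = 500.0
    Lz: float = 100.0
    axis: str = "x"

    def __post_init__(self):
        if min(self.Lx, self.Ly, self.Lz) <= 0:
            raise ValueError("box edge lengths must be positive")
        if self.axis != "x":
            raise ValueError("loading is supported along x only")

    @property
    def volume(self) -> float:
        return self.Lx * self.Ly * self.Lz

    @property
    def lengths(self):
        return np.array([self.Lx, self.Ly, self.Lz])


@dataclasses.dataclass
class FiberPath:
    """Polyline of one fiber with its sampled morphology."""

    vertices: np.ndarray        # (n, 3) ordered points, ends on the boundary
    theta: float                # global in-plane orientation (radians)
    waviness: float             # sampled W = cos(theta_rel)
    seg_length: float           # nominal segment length (um)

    @property
    def contour_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)))

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.vertices[-1] - self.vertices[0]))


@dataclasses.dataclass
class FiberNetwork:
    """Discrete fiber network: shared node array plus per-segment topology."""

    nodes: np.ndarray           # (N, 3) coordinates (um)
    segments: np.ndarray        # (M, 2) node index pairs
    fiber_id: np.ndarray        # (M,) owning fiber per segment
    fibers: list                # list[FiberPath]
    r_phys: float               # physical fiber radius (um)
    box: BoxDomain
    seed: int

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    @property
    def segment_lengths(self) -> np.ndarray:
        d = self.nodes[self.segments[:, 1]] - self.nodes[self.segments[:, 0]]
        return np.linalg.norm(d, axis=1)

    @property
    def volume_fraction(self) -> float:
        return volume_fraction(self)

    def fiber_node_indices(self, fid: int) -> np.ndarray:
        """Ordered node indices of fiber ``fid``."""
        segs = self.segments[self.fiber_id == fid]
        return np.concatenate([segs[:, 0], segs[-1:, 1]])


def fiber_waviness(path) -> float:
    """Waviness W = end-to-end distance / contour length of a polyline."""
    verts = path.vertices if isinstance(path, FiberPath) else np.asarray(path)
    if verts.shape[0] < 2:
        raise ValueError("need at least two vertices")
    lc = float(np.sum(np.linalg.norm(np.diff(verts, axis=0), axis=1)))
    if lc <= 0.0:
        raise ValueError("degenerate zero-length path")
    ls = float(np.linalg.norm(verts[-1] - verts[0]))
    return min(ls / lc, 1.0)


def volume_fraction(net: FiberNetwork) -> float:
    """Total cylinder volume over box volume (fiber overlaps not subtracted)."""
    if net.segments.shape[0] == 0:
        return 0.0
    total_len = float(np.sum(net.segment_lengths))
    return total_len * math.pi * net.r_phys**2 / net.box.volume


def _clip_step(p, q, lengths):
    """Clip the step p->q (p inside the box) at the first box face crossed.

    Returns the clipped endpoint, or None if q is still inside.
    """
    inside = np.all((q >= 0.0) & (q <= lengths))
    if inside:
        return None
    d = q - p
    t_min = 1.0
    for i in range(3):
        if d[i] > 0 and q[i] > lengths[i]:
            t_min = min(t_min, (lengths[i] - p[i]) / d[i])
        elif d[i] < 0 and q[i] < 0.0:
            t_min = min(t_min, -p[i] / d[i])
    out = p + t_min * d
    # land exactly on the face to machine precision
    for i in range(3):
        if abs(out[i]) < 1e-9:
            out[i] = 0.0
        elif abs(out[i] - lengths[i]) < 1e-9:
            out[i] = lengths[i]
    return out


def _propagate(seed_pt, theta, theta_rel, sign0, l_seg, lengths, max_steps=100000):
    """Zigzag walk from the seed in both directions until the boundary.

    The alternating sign sequence is continuous through the seed point so the
    whole fiber is one coherent zigzag.
    """
    def walk(start, direction_sign, first_parity):
        pts = []
        p = start.copy()
        parity = first_parity
        for _ in range(max_steps):
            ang = theta + (sign0 * parity) * theta_rel
            step = direction_sign * l_seg * np.array(
                [math.cos(ang), math.sin(ang), 0.0]
            )
            q = p + step
            clipped = _clip_step(p, q, lengths)
            if clipped is not None:
                pts.append(clipped)
                return pts
            pts.append(q)
            p = q
            parity = -parity
        raise RuntimeError("fiber walk failed to reach the boundary")

    forward = walk(seed_pt, +1.0, +1)
    backward = walk(seed_pt, -1.0, -1)
    verts = backward[::-1] + [seed_pt] + forward
    return np.asarray(verts)


def generate_network(
    mix: OrientationMixture,
    wav: WavinessDist,
    target_vf: float,
    box: BoxDomain | None = None,
    r_phys: float = 5.0,
    l_seg: float = 25.0,
    seed: int = 0,
    max_fibers: int = 200_000,
    min_segments: int = 3,
) -> FiberNetwork:
    """Add random-walk fibers until the target volume fraction is reached.

    Deterministic for a given seed.  Seed points whose fiber would have fewer
    than ``min_segments`` segments (too close to a corner) are resampled.
    """
    if box is None:
        box = BoxDomain()
    if not 0.0 < target_vf < 0.6:
        raise ValueError("target volume fraction must lie in (0, 0.6)")
    if l_seg >= min(box.Lx, box.Ly, box.Lz):
        raise ValueError("segment length must be smaller than the box edges")

    rng = np.random.default_rng(seed)
    lengths = box.lengths
    seg_xsec = math.pi * r_phys**2

    fibers: list[FiberPath] = []
    nodes: list[np.ndarray] = []
    seg_pairs: list[tuple[int, int]] = []
    fiber_ids: list[int] = []
    total_fiber_volume = 0.0
    target_volume = target_vf * box.volume

    while total_fiber_volume < target_volume:
        if len(fibers) >= max_fibers:
            raise RuntimeError(
                f"volume fraction {target_vf} not reached within "
                f"{max_fibers} fibers"
            )
        seed_pt = rng.random(3) * lengths
        theta = float(
            np.interp(rng.random(), *_cdf_cached(mix))
        )
        w = float(
            np.clip(
                _beta_ppf(wav, rng.random()),
                np.finfo(float).tiny,
                1.0,
            )
        )
        theta_rel = math.acos(min(w, 1.0))
        sign0 = 1.0 if rng.random() < 0.5 else -1.0
        verts = _propagate(seed_pt, theta, theta_rel, sign0, l_seg, lengths)
        if verts.shape[0] - 1 < min_segments:
            continue  # resample: fiber too short to carry the zigzag
        path = FiberPath(verts, theta, w, l_seg)
        fid = len(fibers)
        base = sum(len(n) for n in nodes)
        nodes.append(verts)
        n_pts = verts.shape[0]
        for i in range(n_pts - 1):
            seg_pairs.append((base + i, base + i + 1))
            fiber_ids.append(fid)
        fibers.append(path)
        total_fiber_volume += path.contour_length * seg_xsec

    return FiberNetwork(
        nodes=np.concatenate(nodes, axis=0) if nodes else np.empty((0, 3)),
        segments=np.asarray(seg_pairs, dtype=np.int64).reshape(-1, 2),
        fiber_id=np.asarray(fiber_ids, dtype=np.int64),
        fibers=fibers,
        r_phys=r_phys,
        box=box,
        seed=seed,
    )


# --- small per-distribution caches so fiber-by-fiber sampling stays cheap ---

_cdf_cache: dict = {}


def _cdf_cached(mix: OrientationMixture, resolution: int = 4096):
    key = (mix.mu1, mix.mu2, mix.k1, mix.k2, mix.p, resolution)
    if key not in _cdf_cache:
        grid, cdf = mix.cdf_table(resolution)
        if len(_cdf_cache) > 64:
            _cdf_cache.clear()
        _cdf_cache[key] = (cdf, grid)
    return _cdf_cache[key]


def _beta_ppf(wav: WavinessDist, u: float) -> float:
    from scipy import stats

    return float(stats.beta.ppf(u, wav.alpha, wav.beta))
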