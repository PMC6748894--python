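"""Design of experiments over the network parameters and a gridded surrogate.

Five parameters are varied on a full-factorial grid (fiber modulus, connector
stiffness, collagen volume fraction, mean waviness, orientation dispersion);
each design point regenerates a network at a reduced scale, simulates uniaxial
tension to stretch 2, and stores the stress-stretch curve on a common stretch
axis.  The resulting 6-D table (five parameters + stretch) is interpolated
multilinearly and serves as a cheap stand-in for the full model during
sensitivity analysis and inverse identification.

Parameter-to-morphology mapping: the two family mean orientations and the
family weight are held at their measured values; the dispersion sigma sets a
common concentration k1 = k2 for both families; the waviness mean moves the
beta distribution along the one-parameter family with alpha + beta fixed at
the measured total.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import presets
from .distributions import OrientationMixture, WavinessDist, k_from_sigma_deg
from .mechanics import SolverConfig, SolverError, simulate_network, pk1_curve
from .network import BoxDomain, generate_network

__all__ = [
    "PARAM_NAMES",
    "ParameterBounds",
    "ReducedScaleConfig",
    "SurrogateModel",
    "build_design",
    "derive_seed",
    "run_design",
]

PARAM_NAMES = ("E_fiber", "K", "vf", "waviness", "sigma_deg")


@dataclasses.dataclass(frozen=True)
class ParameterBounds:
    """Lower/upper bounds of the five varied parameters."""

    E_fiber: tuple = (60.0, 300.0)     # MPa
    K: tuple = (0.05, 20.0)            # N/m
    vf: tuple = (0.20, 0.40)           # collagen volume fraction
    waviness: tuple = (0.67, 0.83)     # mean of W
    sigma_deg: tuple = (2.5, 10.0)     # orientation dispersion (degrees)

    def __post_init__(self):
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")

    def as_dict(self) -> dict:
        return {name: tuple(getattr(self, name)) for name in PARAM_NAMES}

    def contains(self, params: dict) -> bool:
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            v = params[name]
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                return False
        return True


@dataclasses.dataclass(frozen=True)
class ReducedScaleConfig:
    """Scale settings for desk-size design runs."""

    box: tuple = (250.0, 250.0, 50.0)
    l_seg: float = 20.0
    r_phys: float = 5.0
    r_eff: float = 0.1
    stretch_max: float = 2.0
    n_stretch: int = 51
    n_increments: int = 20

    @property
    def stretch_axis(self) -> np.ndarray:
        return np.linspace(1.0, self.stretch_max, self.n_stretch)


def build_design(
    bounds: ParameterBounds,
    levels,
    budget: int = 10_000,
    allow_large: bool = False,
) -> list[dict]:
    """Full-factorial design, uniformly spaced per axis, endpoints included.

    ``levels`` is either one integer for all axes or a mapping/sequence of
    per-parameter level counts (ordered as ``PARAM_NAMES``).
    """
    if isinstance(levels, int):
        counts = {name: levels for name in PARAM_NAMES}
    elif isinstance(levels, dict):
        counts = {name: int(levels[name]) for name in PARAM_NAMES}
    else:
        seq = list(levels)
        if len(seq) != len(PARAM_NAMES):
            raise ValueError(f"need {len(PARAM_NAMES)} level counts")
        counts = dict(zip(PARAM_NAMES, (int(c) for c in seq)))
    for name, c in counts.items():
        if c < 2:
            raise ValueError(f"{name}: at least 2 levels per axis required")
    total = int(np.prod([counts[n] for n in PARAM_NAMES]))
    if total > budget and not allow_large:
        raise ValueError(
            f"design of {total} runs exceeds the budget of {budget}; "
            "pass allow_large=True to proceed"
        )
    axes = {
        name: np.linspace(*getattr(bounds, name), counts[name])
        for name in PARAM_NAMES
    }
    design = [
        dict(zip(PARAM_NAMES, values))
        for values in itertools.product(*(axes[n] for n in PARAM_NAMES))
    ]
    return design


def derive_seed(params: dict, master_seed: int) -> int:
    """Deterministic per-parameter-set seed (stable across platforms)."""
    key = ",".join(f"{name}={params[name]:.10g}" for name in PARAM_NAMES)
    digest = hashlib.sha256(f"{master_seed}|{key}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _morphology(params: dict):
    mix = presets.MEASURED_MIXTURE
    k = k_from_sigma_deg(params["sigma_deg"])
    mix = OrientationMixture(mu1=mix.mu1, mu2=mix.mu2, k1=k, k2=k, p=mix.p)
    wav = WavinessDist.from_mean(
        params["waviness"], total=presets.WAVINESS_TOTAL
    )
    return mix, wav


def simulate_parameter_set(
    params: dict,
    scale: ReducedScaleConfig,
    seed: int,
    solver_cfg: SolverConfig | None = None,
):
    """One design-point simulation; returns stress on the common stretch axis."""
    mix, wav = _morphology(params)
    box = BoxDomain(*scale.box)
    net = generate_network(
        mix,
        wav,
        target_vf=params["vf"],
        box=box,
        r_phys=scale.r_phys,
        l_seg=scale.l_seg,
        seed=seed,
    )
    if solver_cfg is None:
        solver_cfg = SolverConfig(n_increments=scale.n_increments)
    res = simulate_network(
        net,
        E_fiber=params["E_fiber"],
        K=params["K"],
        stretch_max=scale.stretch_max,
        r_eff=scale.r_eff,
        cfg=solver_cfg,
    )
    curve = pk1_curve(res).resample(scale.stretch_axis)
    return curve.stress


@dataclasses.dataclass
class SurrogateModel:
    """Gridded 6-D interpolant: five parameters + stretch -> PK1 stress."""

    axes: dict                 # name -> 1-D level array, ordered PARAM_NAMES
    stretch: np.ndarray        # common stretch axis
    stress: np.ndarray         # shape (*levels, n_stretch), MPa
    metadata: dict

    def __post_init__(self):
        expected = tuple(len(self.axes[n]) for n in PARAM_NAMES) + (
            len(self.stretch),
        )
        if self.stress.shape != expected:
            raise ValueError(
                f"stress tensor shape {self.stress.shape} != grid {expected}"
            )
        self._interp = None

    @property
    def missing_cells(self) -> int:
        return int(np.sum(~np.isfinite(self.stress)))

    def _interpolator(self):
        if self._interp is None:
            if self.missing_cells:
                raise ValueError(
                    f"{self.missing_cells} missing cells; re-run failures first"
                )
            points = tuple(self.axes[n] for n in PARAM_NAMES) + (self.stretch,)
            self._interp = RegularGridInterpolator(
                points, self.stress, method="linear", bounds_error=True
            )
        return self._interp

    def evaluate(self, params: dict, stretch) -> np.ndarray:
        """Multilinear interpolation; refuses out-of-grid queries."""
        stretch = np.atleast_1d(np.asarray(stretch, dtype=float))
        pts = np.empty((len(stretch), len(PARAM_NAMES) + 1))
        for j, name in enumerate(PARAM_NAMES):
            pts[:, j] = params[name]
        pts[:, -1] = stretch
        return self._interpolator()(pts)

    def curve(self, params: dict):
        from .mechanics import StressStretchCurve

        return StressStretchCurve(
            self.stretch, self.evaluate(params, self.stretch)
        )

    # ------------------------- persistence -------------------------

    def save(self, path) -> None:
        import json

        import h5py

        with h5py.File(path, "w") as h5:
            ax = h5.create_group("axes")
            for name in PARAM_NAMES:
                ax.create_dataset(name, data=np.asarray(self.axes[name]))
            h5.create_dataset("stretch", data=self.stretch)
            h5.create_dataset("stress", data=self.stress)
            h5.attrs["metadata"] = json.dumps(self.metadata)

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        import json

        import h5py

        with h5py.File(path, "r") as h5:
            axes = {name: h5["axes"][name][...] for name in PARAM_NAMES}
            stretch = h5["stretch"][...]
            stress = h5["stress"][...]
            metadata = json.loads(h5.attrs["metadata"])
        return cls(axes=axes, stretch=stretch, stress=stress, metadata=metadata)


def run_design(
    design: list,
    scale: ReducedScaleConfig | None = None,
    seed: int = 0,
    solver_cfg: SolverConfig | None = None,
    progress=None,
    existing: SurrogateModel | None = None,
) -> SurrogateModel:
    """Run every design point and assemble the surrogate grid.

    Solver failures are recorded as missing (NaN) cells and the run continues;
    pass the partially filled model back via ``existing`` to resume.
    """
    if not design:
        raise ValueError("empty design")
    if scale is None:
        scale = ReducedScaleConfig()
    axes = {
        name: np.unique(np.asarray([p[name] for p in design]))
        for name in PARAM_NAMES
    }
    shape = tuple(len(axes[n]) for n in PARAM_NAMES) + (scale.n_stretch,)
    if existing is not None:
        stress = existing.stress.copy()
        if stress.shape != shape:
            raise ValueError("existing surrogate grid does not match the design")
    else:
        stress = np.full(shape, np.nan)
    failures = []
    for count, params in enumerate(design):
        idx = tuple(
            int(np.searchsorted(axes[n], params[n])) for n in PARAM_NAMES
        )
        if np.all(np.isfinite(stress[idx])):
            continue
        run_seed = derive_seed(params, seed)
        try:
            stress[idx] = simulate_parameter_set(
                params, scale, run_seed, solver_cfg
            )
        except SolverError as err:
            failures.append({"params": dict(params), "error": str(err)})
        if progress is not None:
            progress(count + 1, len(design), params)
    return SurrogateModel(
        axes=axes,
        stretch=scale.stretch_axis,
        stress=stress,
        metadata={
            "master_seed": int(seed),
            "scale": dataclasses.asdict(scale),
            "n_design": len(design),
            "failures": failures,
        },
    )
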