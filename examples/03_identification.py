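"""Inverse identification of constitutive parameters with the genetic algorithm.

Builds a coarse surrogate from an analytic stand-in (so the example runs in
seconds; swap in `fibernet.run_design` for a simulation-backed surrogate),
manufactures a target curve from known parameters, and recovers the free
parameters (collagen modulus and waviness) with the real-coded GA.

Run:  python examples/03_identification.py [--seed 2]
"""

import argparse
import itertools

import numpy as np

import fibernet as fn
from fibernet.surrogate import PARAM_NAMES


def analytic_surrogate(bounds, levels=4, n_stretch=31):
    """A smooth, monotone stand-in for the simulated stress grid."""
    axes = {n: np.linspace(*getattr(bounds, n), levels) for n in PARAM_NAMES}
    stretch = np.linspace(1.0, 2.0, n_stretch)
    shape = tuple(levels for _ in PARAM_NAMES) + (n_stretch,)
    stress = np.empty(shape)
    for idx in itertools.product(*(range(levels) for _ in PARAM_NAMES)):
        p = {n: axes[n][i] for n, i in zip(PARAM_NAMES, idx)}
        recruit = 1.0 / p["waviness"] - 0.02 * (p["K"] - 0.05)
        scale = p["E_fiber"] * p["vf"] / 100.0
        stress[idx] = scale * np.maximum(stretch - recruit, 0.0) ** 2
    return fn.SurrogateModel(axes=axes, stretch=stretch, stress=stress,
                             metadata={"kind": "analytic example"})


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2)
    args = ap.parse_args()

    bounds = fn.ParameterBounds()
    surrogate = analytic_surrogate(bounds)

    truth = dict(E_fiber=210.0, K=1.5, vf=0.31, waviness=0.78, sigma_deg=6.0)
    target = surrogate.curve(truth)
    print("target manufactured from:", truth)

    problem = fn.IdentificationProblem(
        exp=target,
        surrogate=surrogate,
        free={"E_fiber": bounds.E_fiber, "waviness": bounds.waviness},
        fixed={k: v for k, v in truth.items()
               if k not in ("E_fiber", "waviness")},
        settings=fn.GASettings(population=40, generations=60, n_runs=4),
        seed=args.seed,
        from_recruitment=False,
    )
    ident = fn.identify(problem)
    print("identified:", {k: round(v, 3) for k, v in ident.values.items()})
    print(f"objective {ident.objective:.6f} (perfect fit = -1), "
          f"R^2 {ident.r_squared:.4f}")
    print("identifiability (spread across runs / bound range):",
          {k: round(v, 4) for k, v in ident.identifiability.items()})


if __name__ == "__main__":
    main()
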