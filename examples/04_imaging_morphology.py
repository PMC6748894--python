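"""Round trip: morphology -> synthetic image stack -> FFT -> refitted morphology.

Renders a synthetic multi-photon-like stack from a known orientation mixture
and waviness distribution, estimates the orientation histogram by FFT, and
refits the mixture and the waviness beta — the recovered parameters should
match the generating ones.

Run:  python examples/04_imaging_morphology.py [--seed 3]
"""

import argparse
import math

import numpy as np

import fibernet as fn
from fibernet.imaging import fit_morphology


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=3)
    args = ap.parse_args()

    fold = lambda a: (a + 90.0) % 180.0 - 90.0
    mix = fn.presets.MEASURED_MIXTURE
    wav = fn.presets.MEASURED_WAVINESS
    print(f"ground truth: families {fold(math.degrees(mix.mu1)):.1f} / "
          f"{fold(math.degrees(mix.mu2)):.1f} deg, "
          f"waviness mean {wav.mean:.3f}")

    # The FFT histogram measures local tangent directions, so render the
    # orientation stack with nearly straight fibers; waviness is measured
    # separately from traced polylines below.
    straight = fn.WavinessDist(2e5, 1e2)
    stack, _ = fn.render_synthetic_stack(mix, straight, n_fibers=120,
                                         shape=(512, 512), seed=args.seed)
    hist = fn.fft_orientation(stack, n_bins=36)
    print(f"FFT histogram mode at {hist.mode_deg:.1f} deg")

    # traced "fibers": ideal zigzag polylines whose waviness is beta-sampled
    rng = np.random.default_rng(args.seed + 1)
    polylines = []
    for w in fn.sample_waviness(wav, 200, seed=int(rng.integers(2**31))):
        half = math.acos(min(w, 1.0))
        pts = [np.zeros(3)]
        d = 1.0
        for _ in range(8):
            step = 20.0 * np.array([math.cos(d * half), math.sin(d * half), 0.0])
            pts.append(pts[-1] + step)
            d = -d
        polylines.append(np.asarray(pts))
    fit = fit_morphology(hist, polylines)
    m = fit.mixture
    print(f"refit: families {fold(math.degrees(m.mu1)):.1f} / "
          f"{fold(math.degrees(m.mu2)):.1f} deg (weight {m.p:.2f}), "
          f"waviness mean {fit.waviness.mean:.3f}")


if __name__ == "__main__":
    main()
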