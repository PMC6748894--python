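"""Fiber orientation and waviness measurement from image stacks.

Orientation histograms are estimated from grayscale slices by windowed 2-D
FFT: the power spectrum of a fibrous image concentrates along the direction
orthogonal to the fibers, so spectral energy integrated over a radial band
and binned by azimuth (rotated by 90 degrees) yields the fiber orientation
distribution.  A synthetic renderer producing sinusoidal fibers of known
orientation and waviness provides ground truth for validation, standing in
for second-harmonic-generation image stacks.

The morphology fit turns a normalized orientation histogram into the
two-family von Mises mixture (weighted maximum likelihood) and traced
polylines into a beta waviness distribution.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter

from .distributions import (
    OrientationMixture,
    WavinessDist,
    fit_beta,
    fit_mixture,
    sample_orientations,
    sample_waviness,
)
from .network import fiber_waviness

__all__ = [
    "ImageStack",
    "OrientationHistogram",
    "MorphologyFit",
    "render_synthetic_stack",
    "fft_orientation",
    "fit_morphology",
    "load_stack",
    "save_stack",
]


@dataclasses.dataclass
class ImageStack:
    """Grayscale slices with isotropic in-plane pixel size (um/px)."""

    slices: np.ndarray              # (S, H, W) float array
    pixel_size_um: float = 0.5
    slice_spacing_um: float = 0.5

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim == 2:
            self.slices = self.slices[None]
        if self.slices.ndim != 3:
            raise ValueError("stack must be (slices, height, width)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclasses.dataclass
class OrientationHistogram:
    """Normalized fiber-angle histogram on [-90, 90) degrees."""

    bin_centers_deg: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.bin_centers_deg = np.asarray(self.bin_centers_deg, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.bin_centers_deg) < 18:
            raise ValueError("at least 18 angular bins required")
        if self.bin_centers_deg.shape != self.weights.shape:
            raise ValueError("bin/weight length mismatch")
        s = float(np.sum(self.weights))
        if s <= 0:
            raise ValueError("histogram has no mass")
        self.weights = self.weights / s

    @property
    def mode_deg(self) -> float:
        return float(self.bin_centers_deg[int(np.argmax(self.weights))])


# --------------------------------------------------------------------------
# synthetic renderer (validation fixture generator)
# --------------------------------------------------------------------------


def _sine_amplitude_for_waviness(w: float, wavelength: float) -> float:
    """Amplitude of y = A sin(2 pi s / wavelength) with chord/arc = w."""
    if w >= 1.0:
        return 0.0
    from scipy import integrate, optimize

    def arc_ratio(A):
        k = 2.0 * math.pi / wavelength
        val, _ = integrate.quad(
            lambda s: math.sqrt(1.0 + (A * k * math.cos(k * s)) ** 2),
            0.0,
            wavelength,
        )
        return wavelength / val

    return float(
        optimize.brentq(lambda A: arc_ratio(A) - w, 0.0, wavelength * 2.0)
    )


def render_synthetic_stack(
    mix: OrientationMixture,
    wav: WavinessDist,
    n_fibers: int = 40,
    shape: tuple = (512, 512),
    n_slices: int = 3,
    noise: float = 0.05,
    seed: int = 0,
    pixel_size_um: float = 0.5,
    wavelength_px: float = 64.0,
    line_sigma_px: float = 1.5,
):
    """Rasterize sinusoidal fibers with sampled orientation and waviness.

    Returns (ImageStack, ground truth dict with per-fiber 'angles_deg' and
    'waviness' of the fibers of the first slice's sample sequence).
    """
    if n_fibers < 1:
        raise ValueError("need at least one fiber")
    rng = np.random.default_rng(seed)
    H, W = shape
    diag = math.hypot(H, W)
    thetas = sample_orientations(mix, n_fibers, seed).values
    wavs = sample_waviness(wav, n_fibers, seed + 1)
    slices = np.zeros((n_slices, H, W))
    per_slice = np.array_split(np.arange(n_fibers), n_slices)
    angles_deg = []
    for s_idx, fiber_ids in enumerate(per_slice):
        img = slices[s_idx]
        for fi in fiber_ids:
            theta = float(thetas[fi])
            # report on (-90, 90]
            a = math.degrees(theta)
            a = (a + 90.0) % 180.0 - 90.0
            angles_deg.append(90.0 if a == -90.0 else a)
            w = float(wavs[fi])
            amp = _sine_amplitude_for_waviness(w, wavelength_px)
            cx = rng.random() * W
            cy = rng.random() * H
            s = np.linspace(-diag, diag, int(4 * diag))
            undul = amp * np.sin(2.0 * math.pi * s / wavelength_px)
            c, sn = math.cos(theta), math.sin(theta)
            xs = cx + s * c - undul * sn
            ys = cy + s * sn + undul * c
            ix = np.round(xs).astype(int)
            iy = np.round(ys).astype(int)
            ok = (ix >= 0) & (ix < W) & (iy >= 0) & (iy < H)
            np.add.at(img, (iy[ok], ix[ok]), 1.0)
        slices[s_idx] = gaussian_filter(img, line_sigma_px)
    peak = slices.max()
    if peak > 0:
        slices /= peak
    if noise > 0:
        slices = slices + rng.normal(0.0, noise, slices.shape)
    stack = ImageStack(slices, pixel_size_um=pixel_size_um)
    truth = {
        "angles_deg": np.asarray(angles_deg),
        "waviness": np.asarray(wavs, dtype=float),
    }
    return stack, truth


# --------------------------------------------------------------------------
# FFT orientation analysis
# --------------------------------------------------------------------------


def fft_orientation(stack: ImageStack, n_bins: int = 36) -> OrientationHistogram:
    """Orientation histogram from windowed FFT power, averaged over slices.

    The power spectrum is integrated over the radial band [1/64, 1/4] of the
    Nyquist frequency (DC excluded) into azimuthal bins; spectrum angles are
    rotated by 90 degrees to give fiber angles.
    """
    if n_bins < 18:
        raise ValueError("at least 18 bins required")
    slices = stack.slices
    S, H, W = slices.shape
    wy = np.hanning(H)[:, None]
    wx = np.hanning(W)[None, :]
    window = wy * wx
    fy = np.fft.fftshift(np.fft.fftfreq(H))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(W))[None, :]
    radius = np.hypot(fx, fy)
    band = (radius >= 0.5 / 64.0) & (radius <= 0.5 / 4.0)
    # spectrum azimuth -> fiber angle: +90 degrees, folded to [-90, 90)
    ang = np.degrees(np.arctan2(fy, fx)) + 90.0
    ang = (ang + 90.0) % 180.0 - 90.0
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    accum = np.zeros(n_bins)
    flat = True
    for s in range(S):
        img = slices[s]
        img = (img - img.mean()) * window
        if float(np.abs(img).max()) <= 1e-30:
            continue
        flat = False
        power = np.abs(np.fft.fftshift(np.fft.fft2(img))) ** 2
        hist, _ = np.histogram(
            ang[band], bins=edges, weights=power[band]
        )
        total = hist.sum()
        if total > 0:
            accum += hist / total
    if flat or accum.sum() <= 0:
        warnings.warn("constant image stack: returning a flat histogram")
        accum = np.ones(n_bins)
    return OrientationHistogram(centers, accum)


# --------------------------------------------------------------------------
# morphology fitting
# --------------------------------------------------------------------------


@dataclasses.dataclass
class MorphologyFit:
    mixture: OrientationMixture
    waviness: WavinessDist
    single_family: bool
    log_likelihood: float


def fit_morphology(
    hist: OrientationHistogram,
    polylines,
    n_pseudo: int = 20000,
    n_restarts: int = 8,
    seed: int = 0,
) -> MorphologyFit:
    """Weighted mixture MLE on the histogram + beta MLE on traced waviness.

    The histogram likelihood is maximized through a deterministic
    pseudo-sample: each bin center is repeated in proportion to its weight
    (total ``n_pseudo`` angles).  If the histogram is nearly flat the fit
    falls back to a single family and is flagged.
    """
    polylines = list(polylines)
    if len(polylines) < 20:
        raise ValueError("at least 20 traced polylines required for waviness")
    w = hist.weights
    counts = np.round(w * n_pseudo).astype(int)
    ang = np.repeat(np.deg2rad(hist.bin_centers_deg) % math.pi, counts)
    if len(ang) < 100:
        raise ValueError("histogram carries too little mass to fit")
    mix, loglik = fit_mixture(ang, n_restarts=n_restarts, seed=seed)
    single = bool(
        w.max() < 1.5 / len(w) or mix.p >= 0.95 or mix.p <= 0.05
    )
    wvals = np.asarray([fiber_waviness(p) for p in polylines])
    wdist = fit_beta(wvals)
    return MorphologyFit(
        mixture=mix,
        waviness=wdist,
        single_family=single,
        log_likelihood=loglik,
    )


# --------------------------------------------------------------------------
# TIFF IO
# --------------------------------------------------------------------------


def load_stack(path, pixel_size_um: float = 0.5) -> ImageStack:
    import tifffile

    data = np.asarray(tifffile.imread(path), dtype=float)
    return ImageStack(data, pixel_size_um=pixel_size_um)


def save_stack(stack: ImageStack, path) -> None:
    import tifffile

    lo, hi = stack.slices.min(), stack.slices.max()
    span = hi - lo if hi > lo else 1.0
    data = ((stack.slices - lo) / span * 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
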