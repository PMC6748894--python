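"""Reference parameter sets for rabbit carotid adventitia samples.

The morphology of one sample (no. 4) was measured directly from multi-photon
image stacks; its constitutive parameters, and the full parameter sets of the
five remaining samples, were identified inversely from uniaxial stress-stretch
data.  These sets, together with the parameter bounds used for the reduced
(surrogate) model, are collected here so analyses can be reproduced without
retyping numbers.

Units: moduli in MPa, connector stiffness in N/m, lengths in micrometres,
angles in degrees.
"""

from __future__ import annotations

from .distributions import OrientationMixture, WavinessDist

# Orientation mixture fitted to FFT orientation histograms of the imaged
# sample: two fiber families at roughly +/-40 degrees from the loading
# (circumferential) axis.
MEASURED_MIXTURE = OrientationMixture.from_degrees(
    mu1_deg=-38.7, mu2_deg=40.7, k1=8.32, k2=10.03, p=0.31
)

# Beta distribution fitted to waviness of traced fibers (mean ~0.718).
MEASURED_WAVINESS = WavinessDist(alpha=15.78, beta=6.21)

# alpha+beta of the measured fit; held fixed when sweeping the waviness mean.
WAVINESS_TOTAL = MEASURED_WAVINESS.alpha + MEASURED_WAVINESS.beta

# Default box: 500 x 500 x 100 um imaged volume; loading along x
# (circumferential), y transverse in-plane, z thickness.
DEFAULT_BOX_UM = (500.0, 500.0, 100.0)
FIBER_RADIUS_UM = 5.0  # uniform 10 um fiber diameter
SEGMENT_LENGTH_UM = 25.0

# Identified parameter sets per sample.  sigma_deg is the orientation
# dispersion (common to both families); waviness is the mean of W.
SAMPLES = {
    1: dict(E_fiber=163.34, K=1.78, vf=0.2903, waviness=0.757, sigma_deg=5.21),
    2: dict(E_fiber=283.86, K=3.81, vf=0.2853, waviness=0.793, sigma_deg=4.33),
    3: dict(E_fiber=80.64, K=1.06, vf=0.3198, waviness=0.746, sigma_deg=5.86),
    4: dict(E_fiber=297.0, K=0.955, vf=0.371, waviness=0.80, sigma_deg=3.55),
    5: dict(E_fiber=194.6, K=4.4, vf=0.3680, waviness=0.769, sigma_deg=3.98),
    6: dict(E_fiber=70.45, K=1.39, vf=0.2935, waviness=0.757, sigma_deg=6.16),
}

# Bounds of the five varied parameters of the reduced model.
PARAMETER_BOUNDS = {
    "E_fiber": (60.0, 300.0),      # MPa
    "K": (0.05, 20.0),             # N/m
    "vf": (0.20, 0.40),            # collagen volume fraction
    "waviness": (0.67, 0.83),      # mean of W
    "sigma_deg": (2.5, 10.0),      # orientation dispersion, degrees
}
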