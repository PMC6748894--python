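# Methods

This note documents the model and the numerical choices implemented in
`fibernet`. It is the package's own account; every statement here can be
checked against the code and the test suite.

## 1. Morphology statistics

**Orientation.** In-plane fiber angles θ ∈ [0, π) follow a two-family
π-periodic von Mises mixture

p(θ) = (1/π)·[ p·e^{k₁cos2(θ−μ₁)}/I₀(k₁) + (1−p)·e^{k₂cos2(θ−μ₂)}/I₀(k₂) ],

with family means μ₁, μ₂, concentrations k₁, k₂ and weight p. The doubled
angle 2θ makes the density π-periodic (a fiber has no head or tail). The
reference fit has families near −38.7° and +40.7° from the loading
(circumferential) axis (`presets.MEASURED_MIXTURE`).

The scalar dispersion σ reported in degrees uses the circular standard
deviation of the doubled angle, halved: σ² = 1 − I₁(k)/I₀(k) on the doubled
scale, and σ_deg = degrees(σ)/2 (`sigma_deg_from_k` / `k_from_sigma_deg`).
When a parameter sweep varies a single dispersion, both families share one
concentration k obtained from σ_deg by this map, with the means and weight
held at the measured values.

**Waviness.** Fiber waviness W = l_s/l_c (chord over contour; 1 = straight)
follows a beta distribution on (0, 1]. The measured fit has α = 15.78,
β = 6.21. Sweeps of the waviness *mean* hold the total concentration
α + β = 21.99 fixed (`WavinessDist.from_mean`), so the sweep changes location
but not the sharpness of the distribution.

Sampling is inverse-transform from tabulated CDFs; all fits are maximum
likelihood (multi-start EM-type ascent for the mixture; `scipy.stats.beta`
MLE with fixed support for the waviness).

## 2. Network generation

Networks are grown in a box (default 500 × 500 × 100 µm; loading along x) by
a random walk until a target collagen volume fraction is reached:

1. draw a seed point uniformly in the box;
2. draw the fiber angle θ from the mixture and waviness W from the beta;
3. set the zigzag half-angle θ_rel = arccos W, so the chord-to-contour ratio
   of the ideal zigzag equals W;
4. propagate segments of length l_seg (default 25 µm) from the seed in both
   directions, alternating ±θ_rel about the fiber direction, until each end
   crosses a box face; ends are clipped exactly onto the face;
5. repeat until Σ(fiber volume) ≥ target_vf · box volume, with fiber volume
   = π r_phys² × contour length (r_phys = 5 µm).

Fibers are planar (z fixed at the seed's z): the polar angle is neglected, so
all mechanics is two-dimensional per fiber plane. Fibers that would have
fewer than three segments (seed too close to a corner) are resampled.
Fiber–fiber cross-linking and contact are not modeled.

## 3. Mechanical model

**Elements.** Each segment is a geometrically exact corotational truss
(engineering strain on the deformed chord). Interior fiber joints carry a
discrete angular spring that penalizes the change of the joint angle from its
as-generated value, with stiffness EI_eff/l_seg. Bending uses the
reduced-radius convention: axial stiffness EA uses the physical radius
(EA = E·π·r_phys²), while bending uses an effective radius r_eff = 0.1 µm,
giving EI_eff = E·(r_phys/r_eff)²·π·r_eff⁴/4. This substitution keeps EA
while making bending essentially negligible — the network response is
invariant to r_eff over (0.05, 0.2) to better than 0.5 % (tested), and
segments behave like stabilized trusses rather than beams.

**Axial law.** The axial force is tension-dominant:
N = EA·ε in tension, N = c·EA·ε in compression with c = 10⁻³, blended
smoothly (C¹, quadratic) over a transition strain of 2×10⁻². Rationale: with
the reduced bending radius a segment's Euler load π²EI_eff/l² is ~10⁻⁵ of EA,
so compressed segments buckle essentially immediately; the reduced
compressive stiffness is the truss-level surrogate for that. The blend width
is numerical regularization only: sweeping it over 10⁻³…2×10⁻² changes the
global response by < 10⁻⁵ relative (ledger of the development record), while
the wide blend removes Newton creep near the slack/taut switch.

**Units.** Lengths in µm, forces in µN, moduli in MPa (= µN/µm²). A connector
stiffness quoted in N/m is numerically identical in µN/µm.

## 4. Boundary conditions

Uniaxial tension along x at global stretch λ = 1 + u_circ/Lx:

- loaded face x = Lx: u_x = u_circ (ramped); fixed face x = 0: u_x = 0;
- a single **pivot** degree of freedom governs transverse contraction. Nodes
  on the lateral faces y ∈ {0, Ly} have u_y = ±u_pivot (bidirectional
  coupling: their reactions load the pivot). Nodes on the loaded/fixed faces
  follow the ramp u_y = ((y − Ly/2)/(Ly/2))·u_pivot as a *follower* grip
  condition whose reaction is external (taken by the grips) and does not load
  the pivot;
- the pivot is tied by a spring of stiffness K to a driven node that follows
  the affine incompressible motion u_aff = (λ^{−1/2} − 1)·Ly/2. Small K
  leaves the pivot nearly free; large K forces affine transverse contraction.
  (Verified: λ_t rises monotonically with K and approaches λ^{−1/2}.)
- lateral-face nodes have free axial displacement;
- out-of-plane displacements are identically zero: with planar fibers the z
  equations carry no stiffness and would be singular.

**A structural limitation, documented deliberately.** Because lateral-face
nodes are axially free, a fiber that does not span both loading faces can
translate axially force-free: it is loaded only through the transverse
contraction, so it under-rotates relative to the affine prediction and never
straightens completely. In a typical box only ~15 % of fibers span both
loading faces, so network-average reorientation saturates well short of the
affine angle and the average waviness at λ = 2 plateaus around 0.8 rather
than approaching 1. This cannot be fixed within the model family: tethering
lateral fiber ends to the macroscopic axial motion u_x = (λ − 1)·x makes
those fibers taut, and their combined transverse pull (mN scale, set by EA)
then dwarfs the connector spring over its entire physical range
(0.05–20 N/m ≈ µN/µm scale). The pivot either collapses (λ_t → 0, if the
lateral reactions load it) or is pinned to the affine drive for every K (if
they are reacted externally) — in both cases K can no longer steer the
transverse kinematics between the free and affine limits, which is the
defining role of the connector and the axis along which all parameter studies
and identifications run. We therefore keep the axially free lateral faces,
retain the K-steering behavior (λ_t rises monotonically with K toward
λ^{−1/2}; verified), and report the reorientation/straightening magnitudes of
the model as they are.

The reported stress is first Piola–Kirchhoff: the loaded-face axial reaction
divided by the undeformed cross-section A₀ = Ly·Lz.

## 5. Solution procedure

Load is applied in increments. Each increment starts from the affine
predictor and is corrected by damped Newton iteration:

- the inner problem (clamp-face ramp frozen) is conservative; Newton steps on
  the reduced unknowns (free DOFs + pivot) use an analytic tangent, Levenberg
  damping that persists across iterations (grows on cut-back steps in the
  slack regime, decays to zero on full steps, recovering quadratic
  convergence), and an Armijo backtracking line search on the total
  potential;
- convergence is relative to the internal force scale ‖f‖ + K·|u_pivot −
  u_aff| measured on the *unprojected* force vector (reaction DOFs included),
  with an absolute floor of 10⁻⁹·EA;
- the clamp-face ramp value must equal the converged pivot displacement;
  an outer Aitken-relaxed fixed point enforces this to 10⁻⁷·Ly (typically
  2–3 outer iterations per increment);
- failed increments are retried with halved steps (up to 8 cutbacks).

A tiny proportional stabilization (10⁻⁹ of mean EA/l per DOF, anchored at
the previous increment) regularizes force-free mechanisms of slack fibers.

The solver is verified against closed-form single-fiber solutions, energy
consistency (external work vs stored energy), and an independent brute-force
oracle that minimizes the same total potential with L-BFGS (`tests/`).

## 6. Response metrics

- **Stress–stretch curve** P(λ) and **final slope** (least-squares slope over
  the last 10 % of stretch).
- **Recruitment stretch**: the stretch at the maximum rate of change of the
  local slope (peak second difference of P on a uniform λ grid); for a single
  zigzag fiber this reproduces 1/W (tested).
- **Reorientation**: per-fiber end-to-end (chord) angle history; percentage
  reorientation |θ₀ − θ|/θ₀; refit of the two-family mixture to final
  angles.
- **Straightening**: per-fiber W = chord/contour on the deformed geometry,
  network average per increment.
- **Non-affinity** NA(r): for each probe neighborhood of radius r (default
  l_seg), a local affine field is least-squares fitted to the displacements;
  NA is the mean squared deviation of the fitted (ε₁₁, ε₂₂, ε₁₂, ω₁₂) from
  the global affine values. NA = 0 under exactly affine fields (tested).
- **Rupture probability**: fit of the per-segment strain distribution at a
  target macroscopic stress (1 MPa by default) and tail probability beyond a
  critical strain.

## 7. DOE, surrogate, sensitivity, identification

A full-factorial design over (E_fiber, K, vf, waviness mean, σ_deg) within
the documented bounds produces stress–stretch curves; responses are stored on
the grid and interpolated multilinearly in normalized coordinates with a
leading stretch axis (`SurrogateModel`, `scipy` RegularGridInterpolator).
Failed cells are NaN and can be recomputed on resume; interpolation refuses
designs with missing cells.

Sensitivity uses OLS (statsmodels): a 6-term linear model on normalized
parameters, and a quadratic model with interactions pruned by p > 0.05.

Identification minimizes the negative R² of the surrogate curve against a
measured curve (`objective`, bounded by −1 ≤ obj) with a real-coded genetic
algorithm (tournament selection, blend crossover, Gaussian mutation, elitism,
multiple independent runs). `scipy.optimize.differential_evolution` is used
in the tests as an independent cross-check, never as the implementation.

## 8. Imaging

Synthetic image stacks of the network are rendered as anti-aliased line
drawings. Orientation histograms are estimated by FFT: the power spectrum is
integrated over a radial band (1/64–1/4 Nyquist, Hann window, DC excluded)
per angular bin; image-plane angles map to fiber angles by a 90° rotation.
Morphology fitting runs the mixture MLE on the histogram and the beta MLE on
waviness of traced polylines. End-to-end recovery (generate → render →
estimate → fit) is tested to within 5° in family means and 0.05 in waviness
mean.

## 9. Randomness and reproducibility

Every stochastic routine takes an integer seed. Batch drivers derive child
seeds with `numpy.random.SeedSequence`, truncated below 2³¹. Identical seeds
reproduce identical networks, simulations, and fits bit-for-bit on one
platform.
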