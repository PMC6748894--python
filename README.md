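# fibernet

Discrete stochastic modelling and mechanics of adventitial collagen fiber
networks.

`fibernet` reconstructs planar collagen networks from measured morphology
statistics (a two-family π-periodic von Mises orientation mixture and a beta
waviness distribution), solves their response to uniaxial tension with a
geometrically nonlinear finite-element solver, and provides the surrounding
analysis machinery: micro/macro response metrics, a full-factorial design of
experiments with a gridded surrogate, sensitivity regression, a real-coded
genetic algorithm for inverse parameter identification, and FFT-based
morphology measurement from image stacks.

The scientific background, model assumptions, and numerical choices are
documented in [docs/methods.md](docs/methods.md).

## Quick start (library)

```python
import fibernet as fn

# 1. Morphology: measured orientation mixture and waviness distribution
mix = fn.presets.MEASURED_MIXTURE              # families near -38.7 / +40.7 deg
wav = fn.WavinessDist.from_mean(0.80, total=fn.presets.WAVINESS_TOTAL)

# 2. Generate a network in a 400 x 400 x 80 um box at 37.1% volume fraction
net = fn.generate_network(mix, wav, target_vf=0.371,
                          box=fn.BoxDomain(400.0, 400.0, 80.0),
                          r_phys=5.0, l_seg=25.0, seed=11)

# 3. Simulate uniaxial tension to a global stretch of 2
res = fn.simulate_network(net, E_fiber=297.0, K=0.955, stretch_max=2.0,
                          cfg=fn.SolverConfig(n_increments=40))

# 4. Macroscopic and microscopic responses
curve = fn.pk1_curve(res)                      # first Piola-Kirchhoff stress
report = fn.metric_report(res)                 # final slope, recruitment, ...
evo = fn.orientation_evolution(res)            # fiber reorientation history
w_mean = fn.average_waviness(res)              # straightening history
```

All randomness is controlled by integer seeds; every derived seed stays below
2^31. Units are micrometres, microNewtons and MPa throughout; a connector
stiffness in N/m is numerically identical in µN/µm.

## Command-line interface

The `fibernet` CLI is a thin layer over the library:

```sh
fibernet generate --config net.toml --seed 7 --out net.json   # or .inp/.vtk
fibernet simulate --net net.json --e-fiber 297 --k 0.955 --stretch 2 --out res.h5
fibernet analyze res.h5 --report report.json
fibernet doe --levels 3 --out doe.h5          # full-factorial design + surrogate
fibernet sensitivity doe.h5 --out sens.json   # linear/quadratic regression
fibernet identify --surrogate doe.h5 --data curve.csv --out params.json
fibernet morph stack.tif --out morph.json     # FFT orientation histogram
```

## Repository layout

- `src/fibernet/` — the library:
  - `distributions.py` — orientation mixture, waviness beta, sampling, MLE fits
  - `network.py` — random-walk network generation to a target volume fraction
  - `mechanics.py` — corotational truss + hinge solver, pivot-connector BC
  - `metrics.py` — final slope, recruitment stretch, reorientation,
    straightening, non-affinity, rupture probability
  - `surrogate.py` / `sensitivity.py` — DOE, gridded surrogate, regression
  - `identify.py` — genetic-algorithm inverse identification
  - `imaging.py` — synthetic stack rendering and FFT morphology measurement
  - `io.py` — JSON/INP/VTK network export, HDF5 results, CSV curves
  - `presets.py` — reference parameter sets and bounds
- `examples/` — narrative analysis scripts (start with
  `examples/01_single_network.py`)
- `scripts/acceptance.py` — reduced-scale reproduction of key reference values
- `tests/` — unit, property and acceptance tests (`pytest`)

## Testing

```sh
pytest            # full suite
```

The test suite checks the solver against closed-form single-fiber solutions
and a brute-force energy-minimization oracle, the samplers and fitters against
their analytic distributions, and the surrogate/identification stack against
exactly representable synthetic truths.
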