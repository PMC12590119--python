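# amblyosim

Simulation and quantification of visual distortions in amblyopia ("lazy
eye").  People with amblyopia often perceive a sinusoidal grating as wavy or
zigzag lines, grids with uneven bar thickness, or irregular scotomas.
`amblyosim` models such distorted percepts, fits the model to drawing images,
and relates the fitted distortion to contrast-sensitivity deficits and to the
predicted spread of activation on cortical orientation-preference maps.  An
LGN analysis module covers the companion electrophysiology questions
(spatial-frequency tuning at several contrasts, reverse-correlation receptive
fields).

## The model

A simulated percept is a saturated, weighted sum of *cortical filters*:

    P~ = Sat( Σᵢ Wᵢ · Fᵢ ),        Fᵢ = Sat_Tᵢ( Gᵢ + Kᵢ )

where each `Gᵢ` is a sinusoidal grating (orientation θ, spatial frequency f
in cycles/degree, phase φ), `Kᵢ ∈ [−1, 1]` is a dark/light duty-cycle
constant (zero in fellow eyes; negative values thicken dark bars),
`Sat_T` clips to ±T with `T ∈ [0, 2]`, and the outer `Sat` clips the sum to
the display contrast range ±1.  Percept/drawing dissimilarity is the
normalized Laplacian pyramid distance (NLPD): band-pass coefficients of a
Laplacian pyramid are divisively normalized by a local magnitude average,
and the distance is the per-scale RMS coefficient difference averaged over
scales.

Fitting is greedy: start from a grating matched to the stimulus, optimize
its six parameters (θ, f, φ, K, T, W) with Nelder–Mead to minimize NLPD,
then add one filter at a time — previous filters frozen — until the distance
threshold, an improvement floor, or the filter budget stops it.

Downstream metrics:

- **Distortion magnitude** — for stimuli ≥ 3 cpd, filters are split into
  orientation-matched (|θ_S − θ_G| ≤ 5°) and not-matched classes; the score
  is `|W̄_not − W̄_matched| · mean(|K|)`, normalized by the cohort maximum.
- **Contrast-sensitivity deficit** — Gaussian CSF fits per eye,
  `CS(sf) = g0 + g·exp(−(sf−sf_p)²/2σ²)`; deficit = fellow/amblyopic peak
  ratio − 1 (floored at 0).
- **Cortical spread** — on an orientation-preference map, the fellow eye
  drives each pixel by `1 − CircD(O_C, O_S)` (CircD is the 180°-periodic
  orientation distance scaled to [0, 1]); the amblyopic eye sums the same
  response over every fitted grating, Gaussian-weighted by its orientation
  offset from the stimulus (σ = 0.2).  Spread is the count of pixels ≥ 70%
  of the per-eye maximum; the spread ratio is amblyopic/fellow.

Because the original subject drawings and measurements are not publicly
deposited, the `synthetic` module generates all inputs with known ground
truth: distorted drawings from known filter sets (plus hand-tremor jitter
and pixel noise), CSF tables, band-pass-noise orientation maps with
realistic pinwheel structure, and a seven-subject cohort whose deficit is
generatively linked to its distortion.

## Worked example

```python
import numpy as np
from amblyosim import (FilterSet, FitConfig, Geometry, GratingParams,
                       fit_percept, make_grating)
from amblyosim.synthetic import SyntheticDrawingSpec, gen_drawing

geometry = Geometry(extent_deg=3.2, pixels_per_degree=40.0)   # 128 x 128
stimulus_params = GratingParams(orientation=0.0, spatial_frequency=5.0)
stimulus = make_grating(stimulus_params, geometry)

# a "drawing": stimulus-matched filter plus a 30-degree interference grating
truth = FilterSet(
    [stimulus_params.with_(duty_constant=-0.3),
     GratingParams(30.0, 5.0, phase=120.0, duty_constant=-0.25)],
    np.array([0.8, 0.3]),
)
drawing, _ = gen_drawing(SyntheticDrawingSpec(truth, rng_seed=1), geometry)

fit = fit_percept(drawing, stimulus, stimulus_params,
                  FitConfig(nlpd_threshold=0.05, max_filters=4, rng_seed=0))
print(f"final NLPD {fit.final_nlpd:.3f} with {fit.n_filters_used} filters")
for p, w in zip(fit.filter_set.filters, fit.filter_set.weights):
    print(f"  theta={p.orientation:6.1f}  sf={p.spatial_frequency:4.2f} cpd"
          f"  K={p.duty_constant:+.2f}  W={w:.2f}")
```

prints:

```
final NLPD 0.104 with 4 filters
  theta=   0.2  sf=5.00 cpd  K=-0.46  W=0.54
  theta=   5.7  sf=5.02 cpd  K=-0.01  W=0.24
  theta=  30.1  sf=5.01 cpd  K=-0.01  W=0.18
  theta= 174.5  sf=5.00 cpd  K=+0.01  W=0.14
```

The first filter recovers the stimulus-matched component (its inflated |K|
absorbs part of the duty-cycle distortion), the 30.1° filter recovers the
planted interference component to a tenth of a degree, and the two
near-matched extras (5.7°, 174.5°) soak up the hand-tremor jitter of the
synthetic drawing.

The end-to-end cohort analysis is one call (or `amblyosim run`):

```python
from amblyosim import run_pipeline
report = run_pipeline({"rng_seed": 1, "pixels_per_degree": 40.0,
                       "max_filters": 2, "map_shape": [80, 80],
                       "map_mm_per_pixel": 3.3 / 80.0})
print(report["deficit_distortion_r"], report["mean_spread_ratio"])
```

which recovers a strong positive deficit–distortion correlation (r ≈ 0.9)
and a mean amblyopic/fellow spread ratio around 1.16 on the default
synthetic cohort.

## Command line

```
amblyosim fit            # fit the percept model to a drawing image
amblyosim csf            # per-eye CSF fits and the deficit
amblyosim distort-metric # distortion magnitude from fit results
amblyosim spread         # cortical activation spread on a map
amblyosim tuning         # LGN spatial-frequency tuning fits
amblyosim synth          # synthetic fixtures (drawings, csf, maps, cohort)
amblyosim run            # end-to-end synthetic cohort -> JSON report
```

Images travel as lossless CSV grids (or 8-bit PNG for inspection) with a
sidecar JSON carrying `{extent_deg, pixels_per_degree}`; orientation maps as
CSV with `{mm_per_pixel}`; results as sorted-key JSON.

## Acceptance script

`scripts/acceptance.py` recomputes the analytic worked values of the
cortical-response model — the circular orientation distance at 90° and 0°
separations and the fellow-eye pixel response at orthogonal and matched
orientation preferences — by running the package's own operations on freshly
generated inputs:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
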