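# Methods

This note documents the models implemented in `amblyosim`, the numerical
choices behind them, what the synthetic data emulate, and the limits of what
a passing test establishes.

## Percept model

A percept is `P~ = Sat(Σ Wᵢ·Fᵢ)` with cortical filters
`Fᵢ = clip(Gᵢ + Kᵢ, −Tᵢ, +Tᵢ)` built from sinusoidal gratings `Gᵢ`.
Conventions: orientation in degrees with 0° = horizontal bars (luminance
modulated along the vertical axis), period 180°; phase in degrees with a
zero-crossing at the field center; spatial frequency in cycles/degree.  The
stimulus field is a 3.2°-diameter circular aperture; outside the aperture
the image is 0 (mean-luminance background).  Filters always span the full
stimulus field.  The default grid is 256×256 (80 px/deg, Nyquist 40 cpd,
comfortably above the 16 cpd stimulus maximum); analyses in the test suite
run at 128×128 (40 px/deg) to fit a single-CPU budget, which still leaves
8 samples per cycle at 5 cpd.

The outer saturation bound is the display contrast range ±1, implemented as
hard clipping; a tanh soft-saturation variant is available behind the
`soft=True` flag of `synthesize_percept` because the original formulation
does not pin down the saturation shape.

`filter_weight` implements the stimulus-drive weight `W = A · Avg(S·G)` as
the zero-lag normalized cross-correlation (mean elementwise product over the
aperture): a matched grating yields ≈ 0.5 (mean of sin²), an orthogonal one
≈ 0.  Note that this quantity nearly vanishes for any filter whose
orientation differs from the stimulus, so it cannot set the *contribution*
of off-orientation filters; consistently with the six optimized parameters
of the model (orientation, phase, spatial frequency, duty cycle, saturation
threshold, weight), the fitter treats the weight `W ∈ [0, 1.5]` as a free
parameter and `filter_weight` serves as a stimulus-drive diagnostic.
`initialize_from_stimulus` therefore starts with weight 1, which makes the
initial percept reproduce the stimulus exactly.

## NLPD

The perceptual distance builds a Laplacian pyramid (5-tap binomial kernel
[1,4,6,4,1]/16, blur–downsample / pad–interleave–blur upsample; depth
`floor(log2(side)) − 2`, i.e. 6 scales at 256², exposed in `NLPDParams`),
divisively normalizes every scale by `0.17 + (3×3 local mean of |coeff|)`,
and averages the per-scale RMS coefficient difference:

    NLPD = (1/N) Σₖ sqrt( (1/Nₛ(k)) Σ (y(k) − ỹ(k))² )

The per-scale RMS reading (rather than dividing the Euclidean norm by the
element count) keeps the metric scale-stable across image sizes and puts
typical stimulus/drawing distances in the 0.1–1.5 range, which is the range
the fit thresholds are quoted in.  Upsampling pads the coarse image *before*
zero-interleaving: reflecting the interleaved grid directly breaks sample
parity at the border and would leak boundary energy into every band (a
constant image must produce exactly zero band-pass coefficients, which is a
test).  The normalization constant and filter are free parameters of
`NLPDParams`; the published reference implementation of the metric could not
be used as a cross-check in this environment, so the test suite bounds the
implementation against an independent loop-based re-implementation of the
same definitions instead.

## Fitting

Greedy filter addition with Nelder–Mead (scipy), previous filters frozen.
Parameters are optimized in an unconstrained vector
[θ, log₂f, φ, K, T, W]; decoding wraps the angles (mod 180°/360°), clamps
K ∈ [−1,1], T ∈ [0.05, 2], W ∈ [0, 1.5], and clamps log₂f to
[0.2 cpd, 0.45·(px/deg)] to stay under Nyquist.  The spatial frequency is
optimized on a log scale because its recovery tolerance is multiplicative.

Seeding matters more than polishing.  Each round builds candidate starts
two ways: (a) *projection seeds* — the residual (drawing minus current
percept) is projected onto the sine/cosine quadrature pair of each
orientation/SF candidate (θ grid of 7.5°; f ∈ {1, 0.8, 1.25}×stimulus),
which yields the optimal phase and an amplitude estimate in closed form;
the amplitude is floored at 0.25 because saturation makes the linear
estimate biased low; (b) a coarse fixed-weight grid over orientation ×
phase.  Candidates are ranked by the true NLPD objective under an
orientation-diversity constraint (≥ 1.5 grid steps apart) so one strong
residual direction cannot crowd out a genuine secondary component; each of
up to 8 survivors gets a short screening Nelder–Mead run (50 iterations),
and the best two get full runs (default 200–300 iterations) followed by a
fresh-simplex restart from the optimum, which recovers from prematurely
collapsed simplices.  Rounds that fail to improve the best NLPD by
`min_round_improvement` are rejected and stop the fit.

The stop threshold is a required, recorded configuration value (default
0.9); the original procedure tuned it per drawing, and the experiments in
this package do the same per experiment — e.g. 0.1 for the synthetic
recovery battery, which sits between the pixel-noise floor (≈ 0.04 at noise
SD 0.02) and typical one-missing-component residuals.

## Distortion, CSF, spread

- Distortion magnitude follows the matched/not-matched weight construction
  with the absolute difference (the alternative signed reading is a flag),
  the 5° matched tolerance, and the ≥ 3 cpd stimulus filter.  Zero-weight
  filters are excluded everywhere (they do not shape the percept), which
  makes the score invariant to padding a fit with inert filters.
  Normalization is cohort-relative (divide by the cohort's maximum raw
  score); single-subject use returns normalized = 1 for a positive score.
- The CSF "peak" is the fitted maximum `g0 + g` (the value at `sf_p`), not
  `g` alone; a config switch exposes the alternative.  Non-convergent or
  flat fits are flagged rather than raised.
- Cortical spread uses `≥ 0.7 × per-eye maximum` (the strict-vs-inclusive
  threshold reading is configurable), per-eye maxima computed
  independently.  In the end-to-end pipeline, fitted filters below weight
  0.1 are excluded from the spread simulation: the response model weighs
  filters only by orientation similarity, so a near-zero-weight spurious
  filter would otherwise count as a full orientation component.
- `map_metrics` estimates the orientation-column width as half the dominant
  wavelength of `e^{2iθ}` — mean and SD are power-weighted statistics over
  the Fourier pixels above half-peak power (no radial binning, which biases
  the estimate) — and counts pinwheels as ±½ phase singularities of the
  doubled angle per plaquette.

## LGN analysis

Tuning curves are fitted with a four-parameter Gaussian in linear SF;
population inclusion uses R² > 0.9.  The low/high split for
contrast-suppression comparisons is 0.2 cpd.  Reverse correlation bins
spikes to 15 ms lags over 19 lags, averages the (±1-recoded) checkerboard
frames preceding each spike, normalizes (subtract mean, divide by max |·|),
then interpolates ×3 spatially (cubic) and re-normalizes so the
max-|value| = 1 contract survives interpolation.  ON/OFF is the sign of the
largest-magnitude STA value.

## Synthetic data: the stated world

- **Drawings**: percept of a known filter set + a two-component sinusoidal
  displacement field (amplitude 0.02° ≈ 1.2 arcmin, 1–2.5 cycles across the
  field) emulating hand-drawing inaccuracy + Gaussian pixel noise (SD 0.02)
  + clipping.  The warp is a minimal tremor stand-in; it reproduces wavy
  lines but not the stroke texture or omissions of real drawings.
- **CSF tables**: Gaussian CSF with fellow-eye parameters (g0 2, g 98,
  sf_p 3 cpd, σ 2 cpd) — ≈ 100 sensitivity at low SF, < 10 at 16 cpd — at
  the five standard stimulus frequencies {1.25, 2.5, 5, 10, 16} cpd with
  multiplicative lognormal noise.
- **Orientation maps**: annular-Gaussian band-pass filtered complex white
  noise, half-angle decoded.  The macaque-like defaults (3.3 mm patch,
  0.79 mm column wavelength) yield measured column widths ≈ 0.38–0.40 mm
  and pinwheel densities ≈ 5–6 /mm², close to the biological patch
  statistics, though the generator has no ocular-dominance coupling.
- **Cohort** (7 subjects, deficits spanning 0.3–3): the amblyopic filter
  set is {matched filter (W 0.8), off filter at 12° + 4°/unit-deficit
  mismatch (W 0.35 + 0.05·d)} with duty magnitude |K| = 0.08 + 0.18·d on
  both filters, parameter noise SD 0.05.  The mismatch stays in the 12–24°
  range where the predicted spread grows with mismatch (beyond ≈ 25° the
  σ = 0.2 similarity weight suppresses the filter's cortical contribution);
  the duty ramp is capped at 0.65 because stronger saturation buries the
  off component below recoverability.  The amblyopic CSF peak is the fellow
  peak divided by (1 + deficit).  A green end-to-end test establishes that
  the pipeline recovers a generatively planted deficit–distortion link
  through fitting, not that real amblyopic cohorts behave this way.

## Known limitations

- The greedy, frozen-history fit can absorb part of a missing component
  into the first filter's weight/duty constant; recovered W and K are
  correlated with the truth but individually biased when saturation is
  strong.
- The deficit–spread correlation of the synthetic pipeline is positive on
  average but noisy at n = 7: the spread ratio is sensitive to ±2–3° errors
  in recovered orientation mismatch.
- No luminance calibration, temporal dynamics, binocular combination, or
  orientation-tuning-width modeling; orientation maps are consumed or
  synthesized, never derived from a developmental model.
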