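# Methods

This note documents the models, parameter choices and numerical decisions
behind `artbox`, and what the synthetic-data generators do and do not
emulate.

## The circular Shepard tone space

A Shepard tone complex is the sum of sinusoids at all octave transposes of
a fundamental that fall inside a fixed component band, here the half-open
interval [30, 16000) Hz. Band membership is half-open so that, e.g., a
500 Hz fundamental contributes 31.25 Hz but not 16000 Hz, giving nine
components. Component amplitudes follow a squared-cosine envelope over
log₂-frequency,

    A(f) = cos²( π (log₂ f − c) / (2h) ),

with `c` the midpoint and `h` the half-width of the log band: 1 at the
geometric band centre (√(30·16000) ≈ 693 Hz), 0 at both edges.

Two design points deserve emphasis:

* **The envelope is fixed relative to the band, not to the fundamental.**
  An envelope that travelled with the fundamental would give degree 360 a
  different spectral weighting than degree 1 and destroy the acoustic
  circularity of the space; with a fixed envelope the amplitude profile
  changes continuously through the 360→1 wrap (asserted in tests).
* **Degree convention.** Degree 1 is anchored at the 278.4375 Hz base
  frequency and each degree multiplies the fundamental by 2^(1/360), so
  f(d) = 278.4375 × 2^((d−1)/360) and degree 360 lies one step below the
  octave (555.80 Hz). This convention reproduces every entry of the
  published tone table at its printed precision.

Component phases are all zero (pure sines), making synthesis deterministic.
Waveforms are peak-normalized to 0.99 and gated with 10 ms raised-cosine
ramps (a conventional anti-click choice; the ramp length is configurable).
All in-band components are kept: the envelope itself drives edge components
to negligible amplitude, so no separate sub-threshold cutoff is applied
(`envelope_threshold` defaults to 0). Audio is written as 16-bit PCM mono
WAV. The auxiliary delayed-match-to-sample tone set is twelve pure tones at
1000 × 2^((i−1)/12) Hz — anchoring tone 1 at 1000 Hz means tone 13, not
tone 12, closes the octave at 2000 Hz — RMS-equalized to their common mean
RMS.

## Circularity assessment

The pipeline mirrors the anchor-based two-set design: each participant set
rates nine tones, three anchor tones 120° apart are shared between sets,
and the two embeddings are merged into one 15-tone configuration.

* **Reverse coding.** Dissimilarity = 5 − mean similarity (scale maximum
  minus rating). Because the coding is linear, averaging participant
  matrices before or after reverse coding is equivalent.
* **MDS.** Metric SMACOF (scikit-learn) initialized from the classical
  Torgerson solution, 300-iteration cap, stress tolerance 1e-9, single
  start. The classical initialization makes the embedding deterministic; no
  random restarts are needed because the majorization starts at the global
  structure already. Raw (unnormalized) metric stress is reported.
* **Affine alignment.** A full 6-parameter least-squares affine map fitted
  on the anchors; with exactly three non-collinear anchors it interpolates
  them exactly, and it admits reflections (MDS orientation is arbitrary).
  After alignment each anchor's two copies are averaged.
* **Spline closure.** A periodic cubic spline through the points ordered by
  their known stimulus degree (available by design), parameterized by that
  degree and sampled at 1000 points. Doubling the sampling changes C by
  < 1e-4 (asserted). Ordering by stimulus degree rather than by embedded
  angle keeps the curve well defined even for distorted configurations.
* **The statistic.** C = 4πA/P² with shoelace area and summed segment
  lengths. It is invariant to rotation, translation, reflection and uniform
  scaling, bounded by 1 (isoperimetric inequality), and matches the closed
  form (π/n)cot(π/n) for regular n-gons to 1e-9. Self-intersecting paths
  are scored on the absolute shoelace area with a warning rather than
  rejected; they do not arise for valid data.

## Mixture models of reproduction error

Errors are wrapped into (−180°, 180°] (the boundary maps to +180°).
Internally angles are radians and densities are per radian, so both pdfs
integrate to 1 over the circle (verified by quadrature to 1e-8).

* **κ ↔ σ mapping.** σ in degrees is converted via the wrapped-normal
  approximation R̄ = exp(−σ_rad²/2), κ = A₁⁻¹(R̄) with A₁(κ) = I₁(κ)/I₀(κ),
  inverted with the standard piecewise seed plus Newton refinement on
  exponentially scaled Bessel functions (no overflow at large κ). The
  mapping saturates: σ beyond ≈150° gives κ ≈ 0.
* **Fitting.** Maximum likelihood with Nelder-Mead on transformed
  parameters — logit for g, stick-breaking for (g, β) so g + β ≤ 1 holds
  implicitly, and a scaled logit confining σ to [0.5°, 100°] — from a grid
  of 10 (standard) or 12 (swap) starting points. The log-density uses
  exponentially scaled I₀ for numerical stability. Fits are invariant to
  permutation of the error list and never fall below the log-likelihood of
  the generating parameters (asserted on simulated data).
* **Simulation.** Exact component sampling: uniform with probability g,
  swap (von Mises centred on a uniformly chosen non-target) with
  probability β, otherwise target-centred von Mises. Important caveat: the
  non-target offsets and the simulator must use independent random streams;
  seeding both from the same integer correlates the offsets with the
  component choices and biases recovery. All built-in drivers derive
  independent sub-seeds with `numpy.random.SeedSequence`.
* Set-size-1 data are fit with the standard model only; the swap model
  requires at least one non-target per trial. Fits can be run per
  participant (default) or pooled.

## Synthetic-data generators

`SimilarityGenSpec` emulates the two-set rating study: 8 ratings per
distinct unordered pair and 2 self-comparisons per tone and participant, 12
participants per set. The mean rating is **linear in circular distance**,
`rating ~ a − b·Δ + N(0, noise)`, rounded half-up and clamped to 0–5, with
defaults a = 4.274, b = 0.01226 — the least-squares line through the
reported group means 3.98 (near pairs) and 1.92 (far pairs) — and noise SD
0.7. The linear form is an assumption of convenience: the true psychometric
similarity-vs-distance function is unknown, and the two reported far-pair
means (2.32 and 1.92) correspond to the *same* circular distance of 168°,
so no distance-driven model can reproduce both; the generator predicts
their midpoint region. Self-pairs draw from N(4.8, 0.3) (clamped), so
almost all synthetic participants pass the ≥4 screening rule;
`n_bad_per_set` plants participants with N(3.0, 0.4) self-ratings for
testing the exclusion path.

One genuine property surfaced by the generator: with **zero** rating noise
the integer Likert rounding quantizes all pair means onto a handful of
levels and the embedding degrades well below C = 0.9. Moderate noise
*helps* — it dithers the quantization so that averaging over 8 repeats and
12 participants recovers the underlying distance gradient. The
`discretize=False` flag provides continuous ratings for idealized checks.

`ReproductionGenSpec` emulates the delayed-estimation design: 18
participants, 4 blocks of 50 trials split evenly between set sizes 1 and 2,
uniform targets on the circle, the probed serial position chosen uniformly,
and errors drawn from the standard model at set size 1 (defaults g = 0.18,
σ = 29.1°) and the swap model at set size 2 (g = 0.18, β = 0.11,
σ = 30.65°) — the reported parameter estimates used as generating values.

What the generators do **not** emulate: reaction times, serial-position or
block effects (parameters are constant within a set size), perceptual
nonuniformity, auditory adaptation or masking, and individual differences
beyond sampling noise. Passing tests therefore show that the pipeline
recovers the structure it assumes, not that real listeners satisfy those
assumptions.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: recovery
studies use 20 seeds × 3000 trials per condition (enough for Monte-Carlo
means of ĝ and β̂ to stabilize within about one percentage point), the
sampling oracles use 10⁵–10⁶ draws, and end-to-end circularity runs use
2–12 participants per set. Every stochastic stage takes an explicit seed;
identical spec + seed reproduces byte-identical tables, and the CLI derives
per-stage sub-seeds from its single `--seed`.

## Known limitations

* The similarity model is linear in circular distance; exponential decay or
  other psychometric forms are not implemented.
* Raw SMACOF stress is reported without normalization, so values are
  comparable only across runs on the same matrix size and scale.
* `fit_swap` assumes a fixed number of non-targets per trial (rectangular
  offset array); mixed set sizes must be fit per condition.
* The circularity statistic treats self-intersecting configurations
  leniently (warning + absolute area); heavily degenerate rating data can
  still produce curves whose C is not meaningful — inspect the stress and
  the configuration plot in such cases.
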