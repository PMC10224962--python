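# Methods

This note documents the models, estimators and numerical choices behind
`dovekie`, and what the synthetic-data validation does and does not show.

## Synthetic call generation

**What it emulates.** Field recordings of little auk calls were made at
48 kHz/16 bit; the published repertoire description reports, per call type,
mean ± SD for nine acoustic parameters (f0 min/max/mean, Q25/Q50/Q75,
duration, AM rate, fM rate) over 30 selected calls per type. The generator
treats each of those rows as an independent Gaussian and offers two levels
of realism:

* `sample_feature_table` draws the parameters directly — the fast path for
  the statistical stages. Draws for physically non-negative quantities are
  redrawn below zero (truncation by rejection, not clipping, to avoid a
  point mass at 0).
* `synthesize_call` renders waveforms: a harmonic stack of 10 partials
  with 1/k amplitude roll-off (the calls show clear harmonic structure;
  the partial count is a modelling default), an f0 contour from the type's
  contour family, sinusoidal amplitude modulation of depth 0.5 at the
  drawn AM rate, raised-cosine gate ramps, and additive Gaussian noise at
  20 dB SNR by default (a clean field recording; configurable).

**Contour families.** Arched pulses for single/clucking/short, a falling
contour for handling, f0 vibrato at half the drawn fM rate for the trill
types (each vibrato cycle contributes two contour inflections), a
3-syllable series for the classic call and a uniformly drawn 2–6-syllable
series for terror calls (85% phonation duty cycle per syllable slot).
Contours are constructed so the phonated time-average equals the drawn f0
mean and the max−min span equals the drawn range. The AM envelope starts
at its minimum so every envelope peak lies strictly inside the call; the
peak-count rate estimator is then unbiased up to duration quantization.

**Derived distributions.** No f0-range row is published; its mean is
(f0 max mean − f0 min mean) and its SD combines the min/max SDs in
quadrature under an independence assumption. Start/end f0, slope and
variation ground truths are computed from the realized contour, not from
published distributions.

**What it does not emulate.** Feature draws are independent within a call
(no published covariance structure), so the synthetic tables lack the
strong f0-parameter correlations of real calls — visible as only ~3
eigenvalues > 1 versus five on the real data. There are no formants, no
vocal-tract model, no colony background noise, no caller identity. One
published oddity is kept as printed: the terror-call Q50 SD (2503.71 Hz)
exceeds its mean (794.57 Hz), so non-negativity truncation shifts that
parameter's sampled mean well above the printed mean; Q50 recovery is
therefore not a validation target.

## Acoustic parameter extraction

**Pitch tracking.** Frame-wise normalized autocorrelation (Hann-windowed,
mean-removed frames; FFT autocorrelation), default 40 ms frames with 10 ms
hop. Peaks in the lag band [1/ceiling, 1/floor] are refined by parabolic
interpolation; defaults floor = 300 Hz, ceiling = 1600 Hz bracket the
species' observed per-type f0 means (≈600–1210 Hz). Candidate salience is
the peak value plus 0.05 per octave above the floor, resolving the
near-tie between the true period and its subharmonic in favour of the
higher candidate; a frame is voiced when its strongest raw peak reaches
0.45. Within each voiced run the final track minimizes
(1 − salience) + 0.25·|log₂(f0ᵢ/f0ᵢ₋₁)| over the top four candidates per
frame (octave-jump smoothing). Calls shorter than four default frames get
proportionally shorter frames (never below 2.5 periods at the floor), so
sub-100 ms clucking calls still yield enough voiced frames. Accuracy on
noiseless harmonic stacks is <0.1% over 400–1400 Hz; on fast arched
contours the voiced-frame mean runs ~2–3% above the contour's true
time-average because low-f0 call edges fall below the voicing threshold —
the same onset/offset censoring a Praat-based measurement would show.

**Contour statistics.** Over voiced frames: min/max/mean, first/last
(start/end), range = max − min, mean absolute slope |Δf0/Δt| (Hz/s), and
f0 variation = cumulative |Δf0| divided by the voiced-span duration
(Hz/s). The latter two are defined here explicitly (the original
measurement script's exact formulas are not published); both are isolated
behind `f0_statistics` for easy substitution.

**Spectral statistics.** Hann-windowed mean periodogram (Welch, 1024-point
segments, half overlap) of the whole call; quartiles interpolate linearly
on the cumulative power distribution; the centre of gravity is the
power-weighted mean frequency. Whole-call (rather than per-frame-averaged)
quartiles are used; the published large Q75 SDs are consistent with
either choice.

**Modulation rates.** AM: analytic-signal envelope, low-pass filtered at
100 Hz (the envelope is even-reflection padded before filtering so the
filter does not smear genuine peaks near the call's onset/offset decay
into shoulders), peaks with prominence ≥ 10% of the envelope maximum,
divided by call duration; a flat envelope gives 0. On ~90 ms calls the
integer peak count quantizes the rate (±½ peak ⇒ ±5 s⁻¹), an inherent
property of the definition that leaves the recovered grand mean a few
percent below the generating rate. FM: sign changes of the 3-point-smoothed frame-to-frame f0
derivative per voiced second.

All measures are amplitude-normalized: a constant gain changes nothing
(property-tested at ±20 dB).

**Spectrograms.** The visual-classification display used a Hann window of
715 samples; the implementation keeps that analysis window and zero-pads
the FFT to 1024 for speed, which densifies the frequency grid without
changing spectral content.

## Repertoire discrimination

Correlation-matrix PCA (features standardized with ddof = 1) — chosen
because the parameters mix Hz, s and s⁻¹ scales; covariance PCA would be
dominated by the high-variance quartiles. A covariance-mode flag is not
offered; the standardization is part of the pipeline contract. Components
with eigenvalue > 1 are retained (first component as a floor in degenerate
cases). The discriminant on retained PC scores is the closed-form
pooled-covariance Gaussian classifier with equal priors (the design is
balanced), which is exactly LDA; it is written in numpy because the
permutation test performs ~240 000 per-fold refits, and is cross-checked
against scikit-learn's `LinearDiscriminantAnalysis` in the tests.

Leave-one-out CV refits scaling, PCA and discriminant on every fold by
default (`leak_free=True`). The common R idiom — global `prcomp` followed
by `lda(CV=TRUE)` — lets the held-out call influence the PCA; that leaky
variant is available as `leak_free=False` and is typically optimistic by a
few points. The permutation test shuffles labels without replacement,
recomputes the full LOO-CCR per shuffle, and reports the add-one p-value
(1 + #{null ≥ observed})/(1 + B), which never reaches exactly zero; the
null mean is the empirical chance level (≈12.5% for eight balanced types).
Rows are canonicalized by `call_id` before any computation so results are
invariant to input row order.

## Valence analysis

Valence is a deterministic map from call type: clucking positive; terror
and handling negative; low trill/short/short-trill likely negative;
single/classic unknown. Only positive/negative calls enter inference
(90 of 240 in the full design).

**MANOVA.** The first five PC scores (from the PCA fitted on the full
table) are responses; valence and call type are predictors. Call type is
nested within valence, so treatment-coded `valence + call_type` is rank
deficient and per-term marginal tests are undefined; sums of squares are
therefore sequential (Type I) with valence first: the valence hypothesis
SSCP is the residual-SSCP reduction from adding valence to the intercept
model, the error SSCP comes from the full model, and error df use the full
design-matrix rank. Pillai's trace (the R `manova` default statistic) is
computed from the generalized symmetric eigenproblem H v = θ(H+E)v with
the standard F approximation. Under null simulations the type-I error is
calibrated at α = 0.05 within binomial tolerance (tested); a one-factor
special case reproduces statsmodels' MANOVA exactly.

**Linear models.** Per parameter, OLS of the raw values on a positive
indicator with negative as reference, via statsmodels: the intercept is
the negative-group mean and the effect the group difference, exactly
(a machine-precision identity that is property-tested); Wald t-based 95%
CIs, R² and adjusted R². Of the eight parameters modelled in the original
analysis, the feature-table fast path carries max/mean f0, range, Q50 and
duration (the published tables provide their distributions); end f0, slope
and variation run through the identical code path on waveform-extracted
tables.

## Validation scales and expectations

The committed validation uses the study's design sizes — 8 × 30 calls,
90-call valence subset — with 1000 permutations in the acceptance script
and 120–200 in the test suite (same check, coarser Monte-Carlo
resolution). Linear-model recovery is averaged over 100–400 seeded
replicates to separate estimator behaviour from single-draw sampling
noise. Expected recoveries, and their known biases, under the generator:
duration intercept ≈ 0.233 s versus the printed 0.22 s (the handling-call
duration SD of 0.10 s is large relative to its 0.11 s mean, so
non-negativity truncation raises the negative-group mean by ≈0.013 s);
extracted clucking f0 ≈ 760–770 Hz versus 751.51 Hz (edge-censoring bias
above); classification CCR on synthetic tables ≈ 55–60% versus 61.7%
reported on the real recordings (independent draws lack the real
covariance structure; the real-data value is not a synthetic-recovery
target).

## Known limitations

* No covariance between features within a call; repertoire eigenstructure
  is flatter than the real data's.
* The selection filter's SNR criterion (call-band 300–8000 Hz RMS over
  flanking-100 ms RMS, in dB) is a stand-in; the original criterion is not
  specified beyond "best available signal-to-noise ratio".
* Multi-syllable calls are analysed as a single unit spanning the whole
  series, matching one-duration-per-call summaries; per-syllable analysis
  is not implemented.
* Arousal, caller identity and individual-level random effects are out of
  scope (unknown in the source design).
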