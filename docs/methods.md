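# Methods

## Stimulus model

An oddball train is `n_standards` identical tones plus one frequency-switched
deviant, all at a fixed repetition rate. "Inter-stimulus interval" here means
the onset-to-onset period (1 Hz ↔ 1 s, 2 Hz ↔ 0.5 s, 4 Hz ↔ 0.25 s),
irrespective of the 100 ms tone duration — the only convention consistent
with those rate/ISI pairs. Tone duration and the 5 ms cosine ramps are
carried as metadata; no audio waveform is synthesized.

Per-tone analysis windows are half-open onset-to-next-onset intervals; the
final (deviant) tone, having no successor, gets a configurable window
(default 1.0 s). This uses all inter-tone signal exactly once. Window
boundaries are mapped to frame indices with a small epsilon
(`ceil((t − t0)·fps − 1e−6)`) so that a frame nominally on a boundary is not
lost to accumulated floating-point error in the time grid.

## Synthetic movie generator

A trial movie is

    F(t,x,y) = F0 · anatomy(x,y) · bleach(t) · [1 + G(x,y) · Σ_n A_n k(t − onset_n)] + ε

with

* `G` — two Gaussian blobs (unit peak) standing in for the low-frequency
  tonotopic fields of A1 and AAF; default geometry 150 × 200 px at 20 fps
  with blob σ = 15 px, matching the acquisition scale of the real recordings.
* `A_n` — the adaptation law `g_opto · (a_∞ + (a₁ − a_∞) e^{−(n−1)/τ})` for
  standards and `a₁ · dev_gain` for the deviant. Defaults: a₁ = 0.08 ΔF/F
  (a typical large widefield response), a_∞ = 0.028 (35% of a₁),
  τ = {5.0, 2.5, 1.25} tones at {1, 2, 4} Hz so that faster rates adapt
  harder, dev_gain = 0.9 so the deviant rebounds to near the first-tone
  level. The light-on factor multiplies standards only; light effects on
  deviants are off by default (configurable), matching the observation that
  interneuron inactivation left deviant responses unchanged. Preset
  profiles: SOM-like {0.70, 0.75, 1.0} (suppression at slow rates) and
  PV-like {1.0, 1.10, 1.15} (enhancement at fast rates).
* `k` — difference of exponentials `e^{−t/τ_d} − e^{−t/τ_r}` normalized to
  unit peak, τ_r = 40 ms, τ_d = 400 ms: generic bulk widefield GCaMP
  kinetics, deliberately not tied to any one sensor variant. At 20 fps the
  sampled peak is within 0.1% of the analytic peak.
* `anatomy` — a static multiplicative random field (SD 15%, 3 px correlation
  length) shared by all trials of a recording. Real movies always carry
  vasculature/expression structure; per-pixel ΔF/F cancels a multiplicative
  static pattern exactly, but it is what makes frame-to-frame motion
  estimation well-posed.
* `bleach` — multiplicative exponential, τ = 300 s (a few percent over a
  trial).
* `ε` — i.i.d. Gaussian camera noise, SD = 1% of F0 per pixel per frame.
  Negative values are clipped at zero and logged.

Trials are interleaved light-off/light-on per rate with fresh noise per trial
and per-trial seeds derived from one root seed; the manifest records a ≥ 30 s
simulated inter-trial gap (recovery from adaptation) as metadata.

An amplitude-level cohort simulator complements the movie renderer for
group-inference studies: per recording it jitters a₁ and τ lognormally
(CV 20% / 15%), the light-on gain additively (SD 0.08), and each trial's
amplitudes multiplicatively (CV 5% — slightly above the 1–4% the movie
pipeline itself produces under default imaging noise), then averages the
configured number of trials. It exercises the quantification, metrics and
statistics layers at cohort scale without the imaging cost.

What the generator does *not* emulate: hemodynamic contamination, optical
PSF, nonlinear indicator saturation, spiking-to-calcium biophysics,
non-rigid motion, and real tonotopic gradients. Passing tests therefore
certify the analysis arithmetic and its statistical behaviour under the
stated model, not robustness to those real-data effects.

## Preprocessing

* **ΔF/F** uses one baseline per trial — the 1 s before the *first* tone
  onset — reused for every tone in the train; within-train baselines would be
  contaminated by the preceding tone's decay. Non-positive per-pixel
  baselines are a hard error naming the affected pixel count.
* **Spatial filter**: radially symmetric 2-D Butterworth magnitude response
  `H(f) = (1 + (f/f_c)^{2·order})^{−1/2}`, applied zero-phase in the
  frequency domain after symmetric padding by half the frame size; defaults
  order 2, cutoff 0.05 cycles/px (both config keys — no published values
  exist to reproduce). DC gain is exactly 1; the filter is linear, so it
  commutes with temporal averaging.
* **Localization map**: mean of 10 consecutive frames (0.5 s at 20 fps)
  starting at the first frame at/after the end of the sound; in the pipeline
  the sound end of the *first* tone is used, since the first response is the
  largest.

## ROI and motion screening

Where the original workflow drew the ROI by hand, this pipeline uses a
deterministic rule: threshold the localization map at 50% of its maximum,
keep the two largest 8-connected components (area ties broken by higher
peak), compute intensity-weighted centroids, and label the centroid farther
along the configured anterior axis AAF, the other A1 (a single detected
region is labeled A1 with a logged warning). A user-supplied mask TIFF can
replace the automatic rule.

Motion screening replaces "obvious motion artifacts" with a quantitative
criterion: for each consecutive frame pair, the integer rigid shift (search
radius ±5 px) maximizing the cross-correlation of Gaussian-smoothed frames
(σ = 1.5 px); a movie is excluded when the largest displacement magnitude
exceeds 2 px (default). Two guards keep the estimator honest on weak frames:
a shift only counts if the normalized correlation at the peak exceeds 0.5
(noise-dominated pairs carry no motion information), and correlations within
1% of the peak are treated as ties resolved toward zero displacement (broad
smooth structure plus pixel noise must not masquerade as motion).

## Amplitude quantification

"Peak–trough" is interpreted as the window maximum minus the window minimum
*at or before* the peak — the rise evoked by that tone — which stays robust
to inter-tone decay at fast rates; `minmax` (max − min anywhere in the
window) is available as an alternative. Trials of one condition are averaged
as traces first, then measured (the default; measuring per trial and
averaging amplitudes is the config alternative). `Control_1` is the
first-tone amplitude of the trial-averaged light-off vector; denominators
below 1e−6 are treated as zero and refused.

The light-on modulation index is the mean over standard tones of the matched
per-tone ratio `On_n/Off_n` (mean-of-ratios; ratio-of-means is a config
switch). Deviants are excluded — light effects on deviants are a separate
question. Matched ratios cancel the indicator-kernel measurement bias
discussed below, which is why gain recovery is unbiased at every rate.

**Known limitation — τ at fast rates.** With a 20 fps camera, any kernel wide
enough to sample its peak accurately necessarily overlaps successive tones at
0.25 s ISI. The peak-trough measure then subtracts a residual that early
tones (with short stimulus history) do not yet carry, steepening the apparent
decay: the exponential fit under-estimates τ by ~25–30% at 2–4 Hz when run
through the movie pipeline. This is a property of non-deconvolved indicator
measurements, not of the fit (deconvolution is out of scope). Parameter-
recovery tests therefore validate τ on trial-averaged amplitude-level
recordings and validate the light-on gain through the full movie pipeline.

The adaptation fit `v_n = a_∞ + (a₁ − a_∞)e^{−(n−1)/τ}` uses multi-start
least squares (τ₀ ∈ {1, 3, 9} tones, tolerances 1e−13) over the standard
tones; a flat input (|a₁ − a_∞| relatively < 1e−6) flags τ as
unidentifiable rather than reporting a meaningless value.

## Statistics

* **Lilliefors gate**: KS distance between the sample and a normal with
  sample-estimated mean/SD (ddof = 1, both one-sided sup terms). The p-value
  is Monte-Carlo exact: `(1 + #{D_mc ≥ D})/(n_mc + 1)` over 10⁴ seeded
  standard-normal null samples of the same size (null tables are cached per
  sample size). Gate level 0.05, the conventional default. Samples passing
  the gate get two-sided t tests; failing samples get Wilcoxon signed-rank
  (zeros dropped, mid-ranks for ties, exact distribution for tie-free n ≤ 25,
  otherwise normal approximation with continuity correction). A sample
  identical to its null value is flagged degenerate with p = 1; a constant
  nonzero paired difference is an error (t undefined).
* **RM-ANOVA**: classic two-way fully-within-subject decomposition with
  subject-by-effect error terms. Greenhouse–Geisser ε per effect is
  `tr(S)²/(d·tr(S²))` with S the covariance of orthonormal-contrast scores,
  clipped to [1/d, 1]; a two-level factor has ε = 1 identically. Corrected
  p-values scale both degrees of freedom by ε. (The standard biased GG
  estimator; no Huynh–Feldt follow-up.) Verified against an independent
  brute-force sums-of-squares oracle and against pingouin.
* **Holm–Bonferroni**: step-down `adj_(i) = min(1, max_{j≤i}(m−j+1)p_(j))`.
  Comparison families are one figure-panel-like unit each: the three per-rate
  one-sample tests of an index form one family, the three across-rate paired
  tests another.
* All tests are two-sided. Recordings are treated as independent units (no
  nesting of recordings within animals — the source analyses did the same;
  a mixed-effects treatment is out of scope).

## Problem sizes and determinism

The test suite and the acceptance script run the movie pipeline on a reduced
60 × 80 px field (same two-blob geometry, scaled) — the quantification is
resolution-independent once the ROI covers the blob — with 4–5 trials per
condition and cohorts of 8–20 recordings; cohort-scale power studies use the
amplitude-level simulator. Every random draw descends from a single root
seed (per-trial seeds are drawn from `default_rng(root)`), identical seeds
give bit-identical movies, and CSV/JSON outputs print floats at fixed
precision so re-runs are byte-identical.
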