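# Methods

This note documents the models, conventions and numerical choices behind
`eeg2tms`, and what the synthetic-cohort tests do and do not establish
about real recordings.

## Preprocessing

* **Resampling** uses polyphase filtering (`scipy.signal.resample_poly`)
  with the rational rate ratio (e.g. 1,000/2,048 = 125/256); only
  downsampling is supported.
* **Band-pass filtering** is a windowed-sinc FIR (Hamming) with transition
  width `min(max(edge/4, 2 Hz), edge)` per edge and length
  `3.3 · fs / width` (odd).  The kernel is symmetric (linear-phase type I)
  and applied by centred convolution, which is exactly zero-phase in one
  pass; passband ripple is far below the ±1 dB contract and stopband
  attenuation reaches ≈53 dB beyond one transition width.  Caveat: for a
  0.1 Hz high-pass edge the implied transition (0.1 Hz) is gentle, and full
  octave-scale attenuation below such an edge would need a kernel longer
  than a desk-scale recording; the 0.1 Hz edge therefore blocks DC and
  drifts rather than delivering 20 dB at 0.05 Hz.  For band edges ≥ 2 Hz
  (all six analysis bands) the 20 dB/octave contract holds comfortably.
* **Epoching** cuts consecutive non-overlapping windows (default 2 s) and
  discards a trailing partial window.  **Rejection** drops an epoch when
  any channel sample exceeds ±100 μV (an all-channel rule: one bad channel
  discards the window).  Surviving original indices are kept so rejection
  history is auditable.
* Ocular ICA and bad-channel interpolation are out of scope; an
  `artifact_hook` lets callers splice an external routine in at the
  conventional position (after rejection).  No re-referencing is applied.

## Band power

Per epoch and channel the Hann-tapered periodogram (density scaling, hence
taper-power corrected) is summed over half-open bins `[lo, hi)` and
multiplied by the bin width, giving mean-square power in μV²; epochs are
averaged afterwards (mean of per-epoch power, not power of the mean
signal).  Half-open bins prevent double counting at the shared band edges
(4, 8, 10, 13, 20 Hz).  With this convention a pure tone of amplitude A
contributes A²/2 to its band and a partition of the spectrum sums to the
total signal power (Parseval; verified to 1–2% in the tests — the residual
comes from taper–signal covariance in finite epochs).  ROI summaries are
arithmetic means over a named channel set; the default ROI is the cluster
around C4 standing in for the right sensorimotor cortex.

## Phase-lag index

Phases come from the analytic signal of the band-filtered epoch (the band
filter reuses the preprocessing FIR contract).  The first and last 10% of
samples per epoch are excluded from averaging (filter/Hilbert edge
transients; fraction configurable).  PLI is computed per epoch and then
averaged across epochs (default), which is less sensitive to phase slips
than pooling all samples; a `pooled` mode is exposed.  `sign(0)` counts as
0, and |sin Δφ| < 1e-9 is treated as zero so that in-phase and anti-phase
lags both yield PLI 0 as the formula implies rather than being decided by
float rounding.

A consequence worth knowing: for band-limited signals the *null* PLI of
independent channels is not 0.  The phase difference decorrelates over
roughly 1/bandwidth, so a 2-s epoch holds only a handful of effective sign
samples, and the epoch-averaged |mean sign| statistic is biased upward
(≈0.25–0.35 for a 3 Hz-wide band).  Planted couplings must therefore be
tested against a Monte-Carlo null from independent channels, not against
zero; the sample-independent-phase null level √(2/(πm)) applies only to
white phase sequences.

## Networks

Electrodes are nodes; PLI is the edge weight.  A sparsity threshold s
keeps the top `round(s·n(n−1)/2)` edges (half-up rounding; ties broken
deterministically toward lower node indices).  Metrics are evaluated on a
sweep (default 0.05–0.50 in steps of 0.05) and integrated to a trapezoidal
AUC, avoiding commitment to a single threshold.

The pipeline default keeps the kept edges **weighted** — the construction
described for this analysis family ("PLI value as the edge weight") — with
shortest-path edge length 1/weight and the geometric-mean (Onnela)
weighted clustering coefficient on max-normalised weights.  The binarised
mode (edge weight 1, printed edge-counting clustering formula) remains
available via `binarize=True` and is the form the closed-form oracles
test.  Disconnected pairs have d = ∞ and contribute 0 to efficiency.
Note that with proportional thresholding the *binarised* global efficiency
at a fixed edge count barely reflects connection strength at all — one
reason the weighted default matters for recovering planted effects.

## Statistics

LASSO uses the 1/(2n) least-squares objective with an L1 penalty
(scikit-learn coordinate descent; cross-checked against both the
closed-form soft-threshold solution on orthonormal designs and R's glmnet
at fixed λ).  Predictors are z-scored internally and the target centred;
coefficients are reported on both scales.  The λ grid is 100 log-spaced
values from λ_max = max_j |x_jᵀy|/n down to 10⁻⁴·λ_max; K-fold CV (default
10, shuffled with an explicit seed) picks the λ minimising mean CV MSE,
ties toward the larger (sparser) λ.  Features with non-zero coefficients
at λ-min are "selected".

Each selected feature is then correlated with RMT and AMT: Pearson if
*both* variables pass Shapiro–Wilk at α = 0.05, otherwise Spearman
(average ranks); p-values are two-sided.  No multiple-testing correction
is applied by default (α = 0.05 per test, matching the analysis family
this mirrors); Benjamini–Hochberg adjustment is available behind a flag.

## Synthetic cohort generator

Each channel is the sum of

* a 1/f-amplitude-spectrum Gaussian background (exponent 1, configurable;
  spectrum flattened below 0.5 Hz), scaled to 1 μV RMS;
* one sinusoid per band whose frequency and phase are re-drawn every 2-s
  coherence block (piecewise-stationary oscillation).  Base amplitudes
  (δ 2.03, θ 1.58, α1 1.68, α2 1.65, β1 1.21, β2 1.00 μV) put band powers
  at magnitudes typical of eyes-closed resting tables; each subject
  multiplies them by a log-normal factor (σ = 0.3, keeps power positive).
  The finite coherence time is essential: an eternal fixed-frequency
  sinusoid per channel lets near-degenerate frequency pairs stay
  accidentally phase-locked for the whole recording, producing spurious
  PLI up to ≈0.9 between "independent" channels;
* planted couplings.  A `CouplingSpec(i, j, band, lag, strength)` mixes a
  shared block-wise oscillation into both channels at a constant lag
  (strength 1 ⇒ PLI exactly 1).  The subject-varying alpha2 structure is a
  `CouplingEnsemble`: channels 0–5 (the C4 cluster plus F4) can share one
  alpha2 oscillation at distinct per-member lags (0.4–2.2 rad, so no pair
  sits at 0 or π); a per-subject latent u ~ Uniform(0, 1) activates
  3 + round(3u) members.  The active clique's pair fraction is the
  subject's true **coupling density**, which the weighted alpha2
  efficiency AUC tracks at r ≈ 0.96;
* artifacts: a +150 μV square pulse across a whole 2-s window in all
  channels, in a seeded random `artifact_epoch_fraction` (default 10%) of
  windows — guaranteed to trip the ±100 μV rule and only that window.

Motor thresholds follow a linear latent model:
RMT = 46.25 − 8·z(true α2 power) − 5·z(coupling density) + N(0, σ),
AMT the same with intercept 32.31; σ defaults to 5 %MSO, which puts
cohort SDs near 11 %MSO.  Negative slopes encode the inverse
power/efficiency → threshold direction.  Everything is reproducible from
`(config.seed, subject_index)` via independent `numpy` seed sequences.

Default study conditions are 32 subjects, 8 channels at 250 Hz, 60 s per
subject — a deliberately desk-scale stand-in for a 128-channel, 10-min
protocol.  The recovery study in the acceptance tests uses 200 subjects,
noise SD 1 %MSO and 20 seeds, so the selection/correlation machinery is
exercised in a regime where failure would be informative rather than
noise-dominated.

**What the generator does not emulate:** head-model mixing (no shared
lead-field between channels beyond the planted couplings), realistic
eye-blink/EMG artifact morphology, non-stationary band power, 1/f slope
variation across subjects, and electrode noise correlations.  Passing the
recovery tests shows the pipeline's statistics recover effects of the
planted kind at the planted size; it does not certify sensitivity or
false-positive behaviour on real recordings.

## I/O and determinism

Recordings are written as 16-bit EDF (1-s records, per-channel physical
scaling; quantisation error < 0.02 μV at cohort amplitudes) with a JSON
sidecar (labels, ROI, seed); reading goes through MNE.  Cohort targets are
CSV, ground truth JSON.  A pipeline run writes every stage output plus a
manifest with the resolved config, package version and SHA-256 per
artifact; identical config + seed reproduce byte-identical artifacts (CSV
floats are formatted with a fixed `%.10g`).

## Known limitations

* Band filtering for connectivity operates on 2-s epochs with kernels of
  comparable length for the lower bands; delta/theta phase estimates from
  2-s epochs are accordingly coarse (a known property of short-epoch PLI,
  not a defect of the implementation).
* The ±100 μV rule is applied to the filtered signal in the pipeline;
  an artifact pulse loses some DC to the 0.1 Hz high-pass but retains
  ≈120 μV, so planted artifacts still trip it.
* `lasso_select` requires n > folds; single-digit cohorts must lower the
  fold count.
* Upsampling, source-space analysis, weighted-PLI variants and
  post-selection inference are out of scope.
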