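# Methods

## The analysis model

The pipeline treats a session as an ordered block protocol — passive
baseline recording, active testing (pulse trains through each laser), and
conditioning stimulation, repeated several times — recorded on one
multichannel grid spanning two cortical areas. Connectivity is quantified
two ways and their relationship is the object of inference.

**Evoked connectivity (SERR).** Pulse-locked epochs are extracted on the
half-open window [0, 30) ms. Delays are trough latencies of the broadband
(0.1–500 Hz, zero-phase Butterworth order 4) bootstrap-averaged waveform
(1000 resamples by default) within [0, 20) ms; ties break toward the
earlier sample, and a flat waveform yields an undefined delay. The delay
distribution across the grid is bimodal — short in the stimulated area
("primary"), 3–6 ms longer in the other ("secondary") — and the class
threshold is placed at the midpoint of the largest gap in the sorted
delays, accepted only if that gap is ≥ 1.5 ms (otherwise the session has
no detectable secondary response and classification fails; a manual
threshold can override). SERR at a secondary site is the per-pulse ratio
of high-gamma (60–200 Hz) peak-to-trough there over the stimulation site,
averaged over pulses (a ratio-of-means variant exists behind a flag). The
stimulation-site channel defaults to the maximal-amplitude primary
channel; a nearest-electrode mode is available. SERR is dimensionless and
exactly invariant to global gain.

**Spectral connectivity.** Magnitude-squared coherence
C_xy(f) = |G_xy|² / (G_xx G_yy), with spectral densities from
Hamming-tapered, demeaned, non-overlapping windows (10 s default),
coherence computed per FFT bin and then averaged within contiguous
half-open 4 Hz bands (DC excluded; theta = [4, 8) Hz). With L windows the
estimator's expectation for independent signals is 1/L — the bias floor —
so only like-for-like differences are interpreted. Band power integrates
the Welch density over a band (a unit sinusoid in-band gives ≈ 0.5 µV²)
and serves as the control that coherence changes are not amplitude
changes.

**Split-window Hebbian regression.** Baseline blocks are cut into
non-overlapping 5 s windows assigned alternately to α (1st, 3rd, …) and β
(2nd, 4th, …) halves, giving two independent coherence estimates. For each
conditioning block with a following baseline, across good-channel pairs
(upper triangle):

    predictor x = C_cond − C_pre,α        (stimulus-evoked coherence)
    response  y = C_post,α − C_pre,β      (baseline-coherence change)

pooled over blocks and fit by OLS. Sharing one baseline estimate on both
sides (the "naive" variant, kept for demonstration) produces a spurious
positive slope under the null; the α/β split removes it.

Two inference details matter and were genuinely open design choices:

* *Block fixed effects.* When several conditioning blocks are pooled, x
  and y are centred within each block. Latent connectivity drifts across
  blocks, shifting block-level means of both variables; without centring
  the across-block covariance of those means can dominate (and even
  reverse) the across-pair relationship the regression targets.
* *Dyadic jackknife standard errors.* Pairs sharing a channel are not
  independent, and per-pair OLS standard errors are badly anticonservative
  (null 95% CI coverage near 75% in simulation at 16 channels). The slope
  point estimate remains plain OLS, but its standard error comes from a
  delete-one-channel jackknife — channels, not pairs, are the exchangeable
  units — with normal reference quantiles, which calibrates coverage to
  ≈ 95% in the package's own null simulations. The regression orientation
  follows "evoked drive predicts baseline change"; a transposed fit is
  available by flag.

**Session- and cohort-level statistics.** Pre/post changes (first vs last
measurement) use paired two-sided t-tests across secondary sites;
zero-variance deltas are reported explicitly (no change → p = 1; constant
shift → flagged, p undefined) rather than as spurious certainty. The
session-level coherence measure is the mean coherence between the
stimulation site and the secondary sites — the pair set the Hebbian drive
actually potentiates (the mean-centred rule conserves total weight, so an
all-pairs average is blind to it). Per-band stimulation-vs-control
comparisons use unpaired two-sided t-tests with Bonferroni correction
(α = 0.05 / n_bands). Dynamics tracks per-block SERR (including SERR of
consecutive 100-pulse conditioning segments, with a linear fit per block),
the baseline-coherence time course, their Pearson correlation, and the
contrast between the last conditioning segment and the following test
block.

## The synthetic generator

One latent nonnegative, symmetric, zero-diagonal matrix `W` (channels ×
channels) drives everything, so every cross-measure regression has known
ground truth:

* *Baseline activity.* Each channel owns a unit-variance theta-band
  (4–8 Hz) Gaussian source; channel i mixes in channel j's source with
  weight `mix_gain · sqrt(W_ij)` (square root ⇒ small-signal coherence
  approximately linear in `W_ij`), plus 1/f-amplitude noise and white
  noise. Default scales: theta source 20 µV SD, pink 10 µV, white 5 µV —
  surface-potential magnitudes with theta coherence in the 0.2–0.4 range
  typical of nearby cortical sites.
* *Evoked responses.* Each 5 ms pulse evokes at every channel a
  difference-of-Gaussians biphasic kernel (trough σ = 1.5 ms, rebound
  σ = 3 ms at 0.35 of trough amplitude, support ≤ 30 ms, unit
  peak-to-trough, trough pinned to the requested delay sample): trough at
  `intra_delay` (6 ms) in the stimulated area and `intra_delay +
  inter_delay_extra` (+4.5 ms) in the other, amplitude `evoked_amp ·
  W[site, j]` (100 µV at the site itself). A shared log-normal per-pulse
  gain (σ = 0.1) models stimulation-efficacy fluctuation without touching
  per-pulse amplitude ratios. With `noise_sd = 0` the output is the exact
  noiseless superposition.
* *Entrainment.* A brief ≤ 30 ms kernel repeated at 5 Hz contributes only
  a line at the pulse rate with a Fourier amplitude of order 0.1 µV —
  invisible against ~25 µV of ongoing theta, and confined to one of the
  ~40 bins a 4 Hz band averages. Physiologically, rhythmic stimulation
  entrains network oscillations; the generator models this as a shared
  narrowband (±1 Hz) oscillation at the pulse rate, received by each
  channel in proportion to its evoked amplitude (`entrain_gain = 2.5`
  source-SD units). This is what makes coherence measured *during*
  stimulation carry the coactivation pattern `a_i·a_j`; its functional
  form is an explicit modelling choice, one admissible way to couple
  stimulation to band-limited coherence.
* *Plasticity.* The Hebbian step is
  `W ← clip(W + η·(A − mean_offdiag(A)), 0, 1)` with `A` the coactivation
  of normalised evoked envelopes (`a = W[site, ·]`, 1 at the site), applied
  after every 100-pulse conditioning segment with η scaled by the
  segment's pulse share — continuous plasticity discretised at the
  segment unit, so evoked amplitudes grow within a block while the
  cumulative block drive equals one η step. `η = 0` is the exact null
  (bit-identical `W`). The default η = 0.75 produces theta-coherence
  increases of a few hundredths to ~0.1 per session — the scale of effect
  the analyses are designed to detect — while staying below the clipping
  regime so doubling η still increases the measured slope. The generator
  applies the rule to the latent envelopes (exact coactivation); the
  estimator that recovers coactivation from the synthesised signal
  (`coactivation_matrix`) is implemented and tested against it.
* *Control sessions* keep baseline and test blocks but replace
  conditioning with passive recording.

**What the generator does not emulate.** Volume conduction and a common
reference (which inflate real µECoG coherence non-selectively),
photoelectric artifacts (except an injectable test spike), electrode
impedance drift and non-stationarity, distance-dependent connectivity on
the grid, evoked-response habituation, and passive decay of potentiated
weights between blocks (the "unlearning" contrast is therefore reported
but near zero on synthetic data). Passing tests show the estimators and
inference are correct under the generative assumptions — not that real
recordings satisfy those assumptions.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `fs` | 1000 | Hz | analysis rate (24 kHz mode exercises the decimator) |
| `intra_delay` / `inter_delay_extra` | 6 / 4.5 | ms | primary trough / secondary extra lag |
| `evoked_amp` | 100 | µV | site peak-to-trough per pulse |
| `source_sd`, `pink_sd`, `noise_sd` | 20, 10, 5 | µV | background composition |
| `mix_gain` | 0.35 | – | baseline-coherence ↔ W coupling strength |
| `entrain_gain` | 2.5 | source SDs | stimulation-entrained oscillation amplitude |
| `eta` | 0 (null) / 0.75 (default effect) | – | Hebbian learning rate |
| `w_max` | 1.0 | – | weight ceiling (prevents runaway potentiation) |
| coherence `window_s` / `band_hz` | 10 / 4 | s / Hz | spectral estimation grid |
| split `window_s` | 5 | s | α/β half-window length |
| `n_boot` | 1000 | – | bootstrap resamples for delay waveforms |
| artifact `threshold_sd` | 8 | robust SDs | pulse-locked artifact flag |

## Numerical and procedural choices

* Anti-aliased downsampling: single 8th-order Chebyshev Type I low-pass
  (0.05 dB ripple, cutoff 0.8 × target Nyquist) applied forward-backward,
  DC gain normalised to 1 (even-order Chebyshev sits at the ripple trough
  at DC), then integer subsampling; rational ratios use polyphase
  resampling. Band-pass filters are 4th-order Butterworth, forward-
  backward (zero phase; a symmetric pulse's trough moves ≤ 1 sample).
* All windows are half-open `[start, end)`; band edges half-open with the
  DC bin excluded; α = 1-based odd windows.
* Coherence matrices are exactly symmetrised, unit-diagonal, clipped to
  [0, 1]; computation in float64 from float32 stored signals.
* Degenerate statistics fail loudly: zero predictor variance raises, a
  flat waveform yields class "none", constant delta vectors are flagged
  rather than given p ≈ 0.
* Sessions store float32 signals in HDF5 (one group per block, protocol as
  JSON attribute, event and channel tables); round-trips are bit-exact.
* Artifact flagging scores the peak within 1 ms of onset against the MAD
  of the [−20, 0) ms pre-onset baseline — an automated, reproducible
  surrogate for visual inspection.
* Two-laser sessions are classified per laser (a channel primary for one
  laser is secondary for the other); test blocks alternate lasers in
  sub-blocks of 10 pulses.

## Study sizes used by the tests and acceptance script

Desk-scale conditions, chosen once from design-time power analysis of the
generator and frozen: Hebbian-regression sessions use 24 channels, three
baseline/test/conditioning repeats plus a final measurement, 90 s
baselines and 120 s conditioning blocks (≈ 830 pair-block observations);
null-calibration sessions 16 channels / 1 repeat / 60 s blocks; cohort
sessions 16 channels / 2 repeats / 120 s baselines, band grid to 60 Hz.
The latent network is fixed across sessions (one synthetic subject);
seeds vary noise and plasticity realizations. At these sizes the null CI
coverage is ≈ 95%, power at the default η is ≈ 100%, and the measured
slope is monotone over {0.5×, 1×, 2×} η.

## Known limitations

* Jackknife inference assumes channels are exchangeable units; a single
  stimulation site concentrates signal on one hub, which the jackknife
  (correctly) prices as uncertainty — power therefore grows with channels
  faster than with pairs.
* The pooled multi-block regression reuses each interior baseline in two
  adjacent blocks (different α/β halves, so responses stay independent,
  but predictor–response cross-correlations of order 1/L remain).
* Coherence-based quantities inherit the 1/L small-sample bias; analyses
  only ever compare like-for-like window counts.
* The entrainment mechanism ties stimulus-evoked coherence to evoked
  amplitudes by construction; alternative couplings (e.g. phase reset of
  existing oscillators) would change the predictor's functional form but
  not the inference machinery.
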