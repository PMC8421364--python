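# Methods

This note documents the models implemented in `thetanest`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer should know about.

## Preprocessing

Raw multichannel LFP (30 kHz in the target recording setup) is
anti-alias filtered and decimated to 1 kHz (chained FIR `decimate` stages
for integer ratios, polyphase resampling otherwise), then each channel is
z-scored over the full trace.  A constant channel cannot be z-scored and
is rejected by name.

## Wavelet analysis

The continuous wavelet transform uses the analytic Morlet wavelet with
center-frequency parameter ω₀ = 6, evaluated in the Fourier domain at
scales `s = 1/(λ f)` with the standard Fourier factor
`λ = 4π/(ω₀ + √(2+ω₀²))`.  Frequency grids are logarithmic, 48 points per
analysis band by default (resolution/cost compromise).  Wavelet power is
**rectified** by dividing energy by scale, so spectral peaks are
comparable across frequencies; `WaveletSpectrum.power` stores
`|W|/√s`.  The cone of influence (e-folding time `√2·s`) is flagged per
time-frequency sample, never trimmed, so indices stay aligned with the
behavioural annotation.

Squared wavelet coherence is the ratio of the smoothed cross-spectrum to
the smoothed auto-spectra.  Unsmoothed wavelet coherence is identically
1, so smoothing is mandatory: boxcar over one theta cycle (1/7 s) in time
and 0.6 octave in scale by default, both configurable.  Points where an
auto-spectrum vanishes are NaN (undefined), not zero.  A Parseval-style
check (total rectified energy ≈ variance, Morlet reconstruction constant
C_δ = 0.776) guards the normalization.

## Spectral Granger causality

Each analysis window gets a bivariate VAR fitted by OLS with intercept.
The order is selected over 1..20 on a common estimation sample and the
chosen order is refit on the full window, so residual statistics match
the sample used by the significance tests.

Geweke's frequency-domain causality is computed from the transfer
function `H(f) = A(f)⁻¹` (explicit 2×2 inverse, preserving exact
structural zeros) after rotating the innovations so the destination noise
is uncorrelated with the source noise.  That rotation splits the
destination spectrum *exactly* into intrinsic and causal parts,

    S_dd = σ_dd |H_dd + (σ_ds/σ_dd) H_ds|²  +  (σ_ss − σ_ds²/σ_dd) |H_ds|² ,
    f_{s→d}(λ) = ln(1 + causal/intrinsic) ,

an additive form that is non-negative by construction and numerically
stable — the textbook subtraction form `ln(S_dd / (S_dd − causal))`
cancels catastrophically when one channel is rescaled or coupling is
strong.  The Geweke identity (mean spectral causality over [0, Nyquist]
equals the time-domain log variance ratio) is used as a consistency
check; note the restricted single-channel model implied by dropping a
channel is ARMA, so its AR approximation uses ~4× the bivariate order.

Two defaults here differ from the obvious first choice, for measured
reasons:

* **Order criterion AIC, VAR estimation at 250 Hz.**  At 1 kHz the GC
  spectrum of a 1-s window cannot localize a 7 Hz directional peak at any
  information-criterion order (the in-band argmax collapses to the band
  edge), and at 250 Hz BIC still under-fits (orders 3–5).  AIC at 250 Hz
  recovers an injected 7 Hz peak with median error < 0.5 Hz.  The
  pipeline therefore decimates to `causality_fs = 250 Hz` for the VAR
  stage; BIC and full-rate estimation remain configurable.
* **Per-direction tests at α/2.**  A window is labeled by two directional
  tests; testing each at raw α would put the expected rate of *any*
  spurious directionality at ~2α.  Bonferroni over the two directions
  controls the per-window family-wise rate at α (measured type-I ≈ 0.06
  at α = 0.05 over 500 noise windows).

Significance defaults to a permutation null (200 circular time-shifts of
the source channel, refit at the fitted order); an asymptotic F-test on
the cross-lag block is provided and is ~50× faster with near-identical
calibration on the synthetic conditions.

Context statistics: windows are assigned to the corridor/sector
containing their midpoint; per (subject, context, direction) proportions
are arcsin-√ transformed; `compare_ratios` fits
`transformed ~ C(sector) + C(corridor)` with a subject random intercept
(statsmodels MixedLM; optimizer sequence lbfgs → powell → cg, OLS
fallback flagged when all fail), reports a Wald F for the sector effect
and all pairwise sector contrasts with studentized-range (Tukey)
adjustment.  Windows labeled "both" count toward both directions by
default (exclusive counting is available).

## EMD and theta cycles

EMD uses classical sifting: cubic-spline envelopes through the local
extrema (plateau-aware `find_peaks`), mirrored-extrema boundary
extension (2 extrema), SD stop criterion 0.2 with at most 10 sifts per
mode, and extraction until fewer than 3 extrema remain.  The residual is
defined as the remainder, so IMFs + residual reconstruct the input to
machine precision.  Each IMF's mean instantaneous frequency is the
amplitude-weighted mean of the analytic-signal phase derivative
(weighting suppresses phase noise where the mode is weak; an unweighted
option exists).  The theta trace sums IMFs with mean frequency in the
closed interval [5, 12] Hz; slower IMFs and the residual form the low
trace, faster IMFs the supra-theta trace.

Theta cycles are delimited trough-to-trough on the theta trace after a
3-sample median deglitch.  A candidate is accepted iff its period lies in
[71, 200] ms *and* exactly one local maximum falls between the troughs
(the single-sinusoidal-wave reading).  Phase zero is the first trough;
`ThetaCycle.trough_idx` coincides with `start_idx` under this
trough-anchored convention, and the span is half-open `[start, end)`.

## tSC extraction

Per-cycle spectral signatures are mean rectified wavelet amplitudes of
the supra-theta trace over the cycle's samples, on a log-spaced
10–200 Hz grid (48 points).  The batch path computes one full-trace CWT
and averages per cycle; the single-cycle path pads by one cycle length to
avoid edge bias — they agree away from trace edges.

Signatures (pooled across both channels of a session by default) are
centered, reduced by PCA to 5 components — the explained-variance
fraction is reported — and unmixed by FastICA.  Three implementation
choices matter:

* **Deterministic whitening.**  PCA scores are already uncorrelated, so
  they are whitened explicitly (divide by SD) and FastICA runs with
  `whiten=False`; this makes the whole fit invariant to sample
  replication, which FastICA's internal SVD is not.  A loading-based sign
  convention on the PCA basis serves the same purpose.
* **Restarts selected by non-negativity.**  FastICA is a local optimizer;
  10 restarts are run from seeds derived from the user seed.  Solutions
  are ranked by the *negative-energy fraction* of the back-projected
  components: tSCs are amplitude spectra — non-negative templates — so
  spurious rotations carry large negative lobes.  Logcosh negentropy was
  tried first and misranked solutions for bounded-amplitude sources.
* **Rotation polish.**  Each candidate is refined by greedy Jacobi plane
  rotations minimizing the negative-energy fraction (the spirit of
  non-negative ICA).  An orthogonal rotation lies within ICA's solution
  ambiguity under model mismatch (five components must also absorb a
  broadband-noise amplitude direction), and the polish reliably moves a
  wrong-basin FastICA solution onto the physical one.

Components are sign-fixed (spectral peak positive), unit-L2-normalized
and labeled tSC1..tSC5 in order of ascending peak frequency; identity
across sessions is by spectral matching, not index.

Strength is the inner product of a raw (uncentered) signature with a
component; it is linear in the signature.  Event thresholds are per-tSC.
The default rule is a **two-means (Otsu) split** of each tSC's strength
distribution: expression is bimodal (a component appears in roughly
15–20% of cycles under realistic nesting), and a mean + 2 SD rule — the
other natural candidate — flags only the ~2% extreme tail, capping
balanced detection accuracy near 0.7 regardless of how well separated the
modes are.  mean + 2 SD and percentile rules remain available for
rare-event regimes.

## Context profiles, clustering, bootstrap

Cycles are assigned to contexts by their trough timestamp.  The profile
matrix stores contexts as rows (32 = 2 areas × 4 corridors × 4 sectors by
default) and tSCs as columns; each context row is normalized to max 1
(z-scoring available), the reading consistent with clustering contexts as
leaves.  Contexts with zero cycles are absent (not zero-filled); rows
from fewer than 10 cycles are flagged low-support.

Hierarchical clustering uses Euclidean distance with average linkage
(UPGMA) by default — single/complete/Ward are accepted — and reports the
cophenetic correlation between the original and tree-implied distances.

Bootstrap support for a context pair resamples cycles with replacement
within every context (preserving context sizes), rebuilds the normalized
profile, re-clusters, and scores whether the two contexts merge as
singletons before either joins any other leaf; 1000 iterations by
default, seed-deterministic, with resamples that empty a context redrawn
(capped).  Note the first-merge criterion divides support among *all*
contexts sharing a motif: in the default synthetic session several
contexts deliberately share their dominant gamma family, so no single
pair reaches high support there — uniquely matched pairs (as in the
planted designs used for validation) do.

## The synthetic generator

The generator's defaults are the study conditions for every recovery
test:

* theta carrier at 7 Hz with ±0.5 Hz slow sinusoidal drift (20 s
  period), phase zero at troughs;
* five gamma burst families at 35/55/80/110/140 Hz, Gaussian-windowed
  sinusoids whose time SD follows the family bandwidth (≈3–5 cycles per
  burst), nested at family-specific theta phases with 0.15 rad phase
  jitter.  Amplitudes rise with frequency (1.0 → 2.2) so each family's
  per-cycle signature contrast is comparable — shorter high-frequency
  atoms would otherwise contribute negligible mean amplitude over a
  cycle;
* context mixing: per corridor/sector context, one dominant family
  (emission probability 0.6 per cycle) over a 0.08 base rate — sparse
  expression, each component in a minority of cycles, as observed for
  theta-nested gamma motifs in vivo and as ICA's non-Gaussianity
  assumption requires.  A burst is emitted with probability equal to the
  weight (with ±25% amplitude jitter) rather than amplitude-scaled
  unconditionally, so per-cycle family membership is well defined as a
  classification oracle.  The chemosensory context c3s3 is pinned to the
  fastest family, mirroring the urine-associated fast-gamma motif;
* 1/f noise (exponent 1) by spectral shaping of white noise, scaled to
  SNR 2 (oscillatory variance / noise variance);
* coupling: channel B is channel A's oscillatory content delayed by 8 ms
  plus independent noise (direction configurable, mirror and
  bidirectional variants).  The delayed-copy construction makes the true
  direction and lag unambiguous *as injected*; note that in the Granger
  sense a weak reverse influence genuinely exists (B's past carries
  independent observations of the shared signal), which is why coupled
  windows are predominantly labeled "both" with A→B dominating.

What the generator does **not** emulate: non-stationary behaviourally
locked theta power, movement artifacts, volume conduction, spike leakage,
electrode drift, inter-subject variability of spectra, and any
within-context temporal structure of the mixing weights.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated generative assumptions, not robustness to every property of in
vivo data.

Stationary VAR processes with specified coefficients provide exact
oracles for the causality stage; their spectral causality is evaluated in
closed form from the true transfer function (`true_spectral_gc`), with no
estimation involved.

The mixed-model power simulation draws binomial window counts
(40 windows/context) at base proportion 0.3 with a +0.2 shift in sector
s3 and subject offsets of SD 0.05 across 8 subjects.

## Problem sizes and determinism

Validation and the acceptance script use: 10⁵-sample VAR realizations for
the estimator-vs-oracle comparison; 500 independent 1-s noise windows for
calibration; a 120-s coupled session (120 windows) for directionality
recovery; a 160-s session (~1050 accepted cycles) for tSC recovery;
planted designs with 300 cycles/context and 1000 bootstrap iterations
(300 in the test suite) for clustering support; 200 simulation
replicates for mixed-model power; and two 40-s full-pipeline runs for
byte-level determinism.  All randomness flows from
`numpy.random.default_rng` seeded from user-supplied seeds; HDF5 outputs
disable timestamp tracking so identical runs are byte-identical.

## Known limitations

* EMD mode mixing is not addressed (no ensemble EMD); the band partition
  by mean instantaneous frequency tolerates moderate mixing because
  misassigned energy lands in adjacent partitions.
* With five spectral families plus a broadband-noise amplitude direction,
  the 5-dimensional PCA representation is overcomplete by one direction;
  the non-negativity selection resolves it in the tested regimes, but
  recovery of a sixth simultaneous family is not possible at n_pca = 5.
* The delayed-copy coupling model conflates "coupling strength" with the
  copied content's SNR; it is an oracle construction, not a biophysical
  claim.
* Bootstrap first-merge support is a stringent pair statistic; motifs
  shared by more than two contexts dilute it by design.
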