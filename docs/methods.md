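# Methods

This note documents the models, conventions and numerical choices behind
`multidfc`, and what the synthetic validation does and does not show.

## Data model and preprocessing

A subject is a T × R matrix of parcellated BOLD values at repetition
time TR (seconds), with per-ROI resting-state-network (RSN) and
hemisphere labels supplied by an atlas table. The atlas defines column
order; a data header that disagrees with it is an error, never a silent
reorder. Preprocessing follows the standard resting-state sequence:

1. **ROI exclusion** — ROIs whose RSN label is the sentinel `"None"`
   (outside every network) are dropped; a 333-ROI parcellation with 47
   such ROIs retains 286.
2. **Uniform ROI selection** (optional) — the ROI set is downsampled
   (286 → 96 in the full-scale geometry) with per-RSN quotas
   proportional to RSN size, forced even so both hemispheres contribute
   equally, taking evenly spaced index positions within each
   (RSN, hemisphere) block. The rule is deterministic; index-uniform
   spacing stands in for spatial uniformity because the artifact works
   on already-parcellated data without coordinates.
3. **High-pass filter** — zero-phase (forward–backward) 5th-order
   Butterworth at 0.01 Hz. The literature the pipeline follows specifies
   only the cutoff; the filter family and order are this package's
   choice, and zero-phase filtering avoids distorting dFC timing.
4. **z-standardization** — per ROI column, population (1/T) variance
   convention. The convention is irrelevant to correlations but is fixed
   for reproducibility; standardization is idempotent to 1e-12.

## Estimators

All methods emit T′ × R × R stacks of symmetric FC matrices
(`DfcMatrix`); asymmetry beyond 1e-10 raises rather than being repaired.

**Sliding window (SW).** The taper is the full discrete convolution of a
60-TR rectangle with a Gaussian kernel (σ = 3 TRs, truncated at ±3σ,
kernel length 19), giving a 78-TR support, normalized to sum 1. Window
positions step by 30 TRs over fully contained placements:
`floor((T − 78)/30) + 1` windows, i.e. exactly 38 for T = 1,200 — the
printed window count is only reproduced when the taper extends the
support, which is why the convolution is full rather than truncated.
Each window yields the taper-weighted Pearson correlation (weighted
means/variances with the taper as observation weights). Time stamps are
fractional window-centre TR indices.

**Time-frequency (TF).** Continuous Morlet transform (ω₀ = 6) at 101
scales log-spaced between Fourier periods 2·TR and T·TR/4. Coherence per
scale–time cell is |S(W_x W_y*/s)|² / (S(|W_x|²/s)·S(|W_y|²/s)) with the
standard cross-wavelet smoothing: Gaussian in time with width equal to
the scale, boxcar across 0.6 octave of scales. Smoothing is linear with
positive weights, so Cauchy–Schwarz bounds the magnitude-squared
coherence in [0, 1] and identical inputs give exactly 1.
Magnitude-squared coherence is the default (`squared=False` switches to
magnitude). The cone of influence uses the e-folding distance √2·s; a
time point averages only over admitted scales, and edge points admitted
by no scale fall back to the unmasked average rather than emitting NaN.
Significance masking of coherence is not applied by default: its role in
the scale averaging is not well defined, and the permutation null in the
comparison framework provides calibration where needed.

**Group-fit / subject-apply contract.** State-based methods fit once on
all subjects (sequences concatenated where the model needs it, with no
transition counted across subject boundaries — HMMs receive per-subject
lengths) and are then applied per subject: labels by the method's native
assignment rule (nearest centroid for CAP/SWC, Viterbi for CHMM/DHMM,
max-|inner product| atom for WL), and the dFC matrix places the state FC
at each time point's label. A subject-level dFC therefore contains at
most K distinct slices. Labels are 1-based; fractional occupancy is the
label histogram normalized to 1.

**CAP.** Two-level k-means (k-means++ with 10 restarts at every stage,
seeded deterministically): per-subject clustering into 20 centroids,
group clustering of pooled centroids into K, then every frame assigned
to its nearest group centroid. All frames are clustered (no
point-process thresholding), following the extended-CAP formulation.
State FC = c·cᵀ (rank 1, trace ‖c‖²).

**SWC.** Features are the R(R−1)/2 lower-triangle values of each SW
window; the same two-level k-means; centroids devectorized with unit
diagonal (correlation convention — the diagonal of a correlation-based
state is 1 by definition).

**CHMM.** `hmmlearn` Gaussian HMM with full covariances, fit on the
concatenated series. Baum–Welch is initialization-sensitive — on
covariance-only regimes the k-means mean initialization carries no
information, and single starts land in poor local optima on a large
fraction of fixtures — so the fit runs 5 EM starts and keeps the highest
final log-likelihood. Covariances get a 1e-6 ridge if an SPD check fails
(on top of hmmlearn's min_covar floor). Decoding is Viterbi (a single
hard state time course is required, not posterior marginals).

**DHMM.** The SWC stage is first run with `n_obs = round(K·16/24)`
states (8 symbols for K = 12); its label sequences are the categorical
HMM's observations. Hidden labels are Viterbi-decoded; each hidden
state's FC matrix is the mean of the clustering-method dFC slices
assigned to it — an occupancy-weighted mean of SWC state matrices.
Hidden states decoded onto no window are dropped with a warning and the
remainder renumbered (recorded in metadata).

**WL.** k-SVD with hard sparsity T₀ = 1, written in-house: sparse coding
assigns each frame to the atom maximizing |⟨d, x⟩|; the dictionary
update takes the leading singular pair of each atom's assigned block
(optimal rank-1 refit, which also refreshes the coefficients); dead
atoms are reinitialized from the worst-represented frame. Both steps are
monotone in ‖X − DMᵀ‖², which is tracked and tested per iteration.
Atoms are stored with their largest-magnitude element positive (outer
products are sign-invariant anyway); state FC = d·dᵀ with trace 1.

## Standardized array and comparison framework

Per-TR methods (TF, CAP, CHMM, WL) are downsampled onto the 38-point
window-centre grid by nearest TR (ties to the earlier TR); nearest
rather than averaging preserves the per-TR state labels exactly. The
assembled `DfcArray` is (S, M, 38, R, R) with label axes, stored in one
HDF5 file together with the YAML configuration and seed that produced
it.

All comparisons use the off-diagonal lower triangle only (the diagonal
is method-dependent: 1 for correlation-based methods, variances for
CHMM, ‖c‖² terms for outer products — it carries no connectivity
information). Averaging order follows the level definitions:
within-subject first, then across subjects; time before subjects for the
spatial level. Spearman is Pearson on average ranks; mutual information
uses a rank transform into 10 equal-frequency bins (bits), with a
warning below 100 samples; Euclidean similarity is reported as a
distance and used directly as the clustering distance. Undefined
correlations (zero-variance connection time courses — routine for
state-based methods) are excluded from averages with counts logged,
never imputed.

**Grouping.** Ward linkage on 1 − correlation (or raw Euclidean
distance, or max(MI) − MI), flat cut at 0.7 × the maximum merge height.
An exactly uniform similarity matrix is special-cased to a single group:
Ward heights for equidistant items all exceed 0.7 × the maximum, so the
cutoff rule alone would shatter structureless input into singletons.

**Rank normalization.** Before variance comparisons, each (subject,
method)'s 38 × C values are jointly replaced by average ranks rescaled
to [0, 1] — jointly over time and connections, the same ranking a
flattened Spearman correlation uses. The transform is idempotent and
invariant to strictly monotone maps.

**Variance decomposition.** `var_time[s,c]` is the variance over the 38
time points averaged over methods; `var_method[s,c]` the variance over
the 7 methods averaged over time; `var_subj[c]` the variance over
subjects averaged over time and method. Variances use ddof = 1: with
only 7 methods the 1/n convention biases the method variance down by
6/7, which would make even perfectly exchangeable data report a ratio of
0.86 instead of 1. Summary ratios average per-cell ratios (cells with
zero denominator excluded); the RSN-pair matrix averages the variances
over each pair's connections *before* the ratio, minus 1, so 0 means
equal variance over method and time.

**Permutation null.** Each permutation independently shuffles the time
axis of every (subject, method) slice — a pure time permutation, so
fractional occupancy is preserved exactly — and recomputes overall
similarity. p-values are one-sided (≥ tail) with the add-one convention
p = (1 + #{null ≥ obs})/(n_perm + 1).

## Synthetic generator and what the tests show

`generate_markov_bold` draws, per subject, a first-order Markov chain
started from its stationary distribution; each TR's observation is the
active state's multivariate Gaussian (mean + Cholesky-transformed noise)
plus optional isotropic observation noise. Generators are pure functions
of (spec, seed). Two fixture families match how the methods encode
states:

* **Covariance contrast** (second-order methods): K = 3 states, zero
  means, state k carrying within-block correlation 0.9 on the k-th RSN
  block (0.1 elsewhere, 0 between blocks), observation noise SD 0.1.
* **Mean patterns** (first-order methods): orthogonal block activity
  patterns (amplitude 3 over noise SD 0.3); for WL the polarity flips
  between paired states so every column stays zero-mean and the planted
  atom direction survives global z-scoring. CAP centroids are scored
  against the conditional means of the standardized data under the true
  labels, because global z-scoring shifts raw patterns; WL atoms and all
  state-FC matrices are scored after Hungarian matching (and CHMM
  covariances after rescaling to correlation, since globally
  standardized data gives states state-dependent diagonal scale).

**Dwell time and windowed recovery.** The default chain uses
self-transition 0.95 (mean dwell 20 TRs), a realistic resting-state
regime. That regime is, however, unidentifiable for window-based state
clustering: a 78-TR window then mixes ~4 dwell segments, and no
separation of the state covariances makes the window features pure (we
measured SWC label accuracy 0.72 at within-block r = 0.9 and *lower*,
0.58, at r = 0.95). The recovery benchmarks therefore use
self-transition 0.99 (mean dwell 100 TRs, exceeding the window) for the
covariance fixture — "well-separated states" for a windowed estimator
necessarily includes dwell times longer than the window — and 0.95 for
the per-TR first-order fixture, where no such constraint exists.

**Problem sizes.** Tests and the acceptance script run the full
seven-method pipeline at 10 subjects × 1,200 TRs × 12 ROIs in 3 RSNs
(K = 3), which exercises every code path of the full-scale geometry
(395 × 1,200 × 96, K = 12) at desk scale; the structural counts of the
full geometry (38 windows, 4,560 connections, 2,765 array cells,
333 → 286 → 96 ROIs) are computed exactly.

**What passing does not show.** The generator emulates Markov-switching
Gaussian covariance structure with RSN blocks. It does not model
hemodynamics (HRF convolution), physiological confounds (respiration,
cardiac cycles, motion), scanner noise spectra, spatial autocorrelation
within parcels, or subject heterogeneity in state sets. Recovery on
these fixtures demonstrates algorithmic correctness and identifiability
under the planted model, not performance on real BOLD; on real data the
true state structure (if any) is unknown and method disagreement is the
object of study, not an error signal.

## Known limitations

* DHMM's observation-symbol count implements the 16/24 ratio literally
  (`n_obs = round(K·16/24)`); `n_obs` is exposed for other readings.
* The WTC scale-average weights every admitted scale equally; no
  significance mask is applied by default.
* `select_uniform_rois` is index-uniform within (RSN, hemisphere)
  blocks; with spatial coordinates a geodesic-uniform rule would be
  preferable.
* Euclidean "similarity" matrices are distances; mixing metrics across
  levels in one grouping is not supported.
* EM multi-start makes CHMM fits slower (×5) but materially more
  reliable; the chosen start is recorded in fit metadata.
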