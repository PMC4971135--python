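# Methods

This note documents the models, numerical choices and synthetic study
conditions implemented in `crydx`, and what its tests do and do not
establish about real cry data.

## Front end

Audio is averaged to mono and pre-emphasized with the first-order
high-pass P(z) = 1 − 0.97 z⁻¹ applied to the whole segment before
framing (the first output sample passes through unchanged, so no sample
before the segment start is needed).  Frames are 10 ms by default (30 ms
available) with 30% overlap; the hop is `round(L·0.7)` samples so frame
counts are exactly reproducible.  Frames are Hamming-windowed, padded to
the next power-of-two FFT size (512 for 10 ms at 44.1 kHz), and their
magnitude-squared spectra pass through 24 triangular filters equally
spaced on the mel scale mel(f) = 2595·log₁₀(1 + f/700) over 0–4 kHz.
The 4 kHz default upper edge reflects where cry energy concentrates
(the cumulative-power analysis in `preprocessing` reproduces this kind
of measurement); a wider band is a config change away.

Cepstra use the plain cosine transform C_i = Σ S_k cos(i(k−½)π/K)
without orthonormal scaling; any constant factor is absorbed by the
GMMs.  The energy feature is the log of the pre-emphasized windowed
frame's sum of squares (C₀ is not used).  Filterbank outputs and energy
are floored at 1e−10 before the log so silence and recording dropouts
never produce −Inf.  Delta and acceleration coefficients use the
regression window with Θ = 2 and edge replication; Θ is configurable.
The energy convention (log frame energy rather than C₀) and Θ are
choices where the method description is silent; both are exposed for
sensitivity analysis.

Labeled segments are cut with half-open sample intervals
[round(start·fs), round(end·fs)) so adjacent labels never share a
boundary sample.  Cry units tile each segment into 3 s chunks; the
trailing remainder is kept and flagged partial by default, because test
recordings of any length must remain scoreable (dataset filter A); the
B/C filters count only full units.

## Mixture models and adaptation

All GMMs are diagonal-covariance.  Likelihoods are evaluated in the log
domain via log-sum-exp.  UBM training is native EM from k-means++
initialization with a variance floor of 1e−3 times the global
per-dimension variance (HTK-style flooring); empty components are
re-seeded at the lowest-likelihood frame; training is bit-reproducible
given a seed.  Mixture sizes are configuration values — experiments
here use small desk-scale models (8–64 components); production-scale
presets in the hundreds are supported but not required by any test.
UBM training data is pooled with per-subclass balancing (equal frame
quotas, seeded subsampling; a subclass short of its quota is upsampled
with replacement) so the dominant healthy class cannot bias the UBM.

The BML sample weight for component k is w(x_t) = f_k(x_t)/F(x_t), so
c_k·w(x_t) is the ordinary posterior.  The per-component weight update
is read as the mean posterior responsibility ĉ_k = (1/T)Σ c_k w(x_t),
which coincides with single-component EM and stays in [0,1]; a literal
self-multiplying variant (`literal_weight_update`) is kept for
comparison because the printed update admits both readings.  After each
weight update the remaining weights are rescaled by (1−ĉ_k)/(1−c_k) so
the simplex constraint always holds.  Components are visited in
descending effective-count order, 2 sweeps of 3 iterations each by
default; components with fewer than 1.0 effective frames are skipped
and keep their UBM values.  The other components' densities are cached
across a sweep and only the updated component's column is recomputed.

MAP adaptation is the classic mean-only update with relevance factor
r = 16.  The coupled method blends BML estimates with UBM values using
the single coefficient αᵢ = nᵢ/(nᵢ+r) for the mean and, via
second-moment matching, for the variance:
Σᵢ′ = αᵢ(Σ̂ᵢ+μ̂ᵢ²) + (1−αᵢ)(Σᵢ+μᵢ²) − μᵢ′².  Methods 1 and 4 leave
variances (and method 1 weights) bit-identical to the UBM's.

## Scoring and evaluation

Both likelihood-ratio terms are duration-normalized (1/T), making
scores invariant to unit length.  The background-set alternative is the
log-mean of duration-normalized per-model scores.  File scores are the
unweighted mean of unit scores (concatenation is available behind a
flag); a recording with no units of a cry type yields an *absent*
score, never zero.  HNORM parameters (imposter mean, population std)
are fitted per detector and cry type on adaptation-split non-target
files only.

Threshold sweeps use the convention score ≥ θ → accept.  EER is
linearly interpolated between the sweep points straddling FAR = FRR;
AUC is the Mann–Whitney statistic with ties counted half; DET normal-
deviate coordinates clip rates to [1e−6, 1−1e−6].  The optimal
operating point computes the cost slope S from the stated costs
(defaults C_FP = C_FN = 0.5, C_TN = C_TP = 0, equal priors, S = 1) and
selects the sweep threshold minimizing expected cost — the operational
form of matching the ROC tangent slope, chosen because finite-
difference slopes of an empirical step-function ROC are 0 or infinite
almost everywhere.

## Fusion

Recordings with both cry types form 2-D score vectors.  The classifier
bank: MLP with one hidden layer of 10 tanh units, softmax/cross-entropy
output, deterministic batch optimization (L-BFGS) capped at 1000
iterations; a Parzen-window PNN with Gaussian spread 0.1 in
standardized-score units; SVMs with linear, inhomogeneous quadratic and
cubic polynomial, Gaussian RBF, and sigmoid ("MLP") kernels — the
sigmoid kernel is tanh(γ⟨x,x′⟩ + c₀) with γ = 1, c₀ = −1.  Inputs are
standardized with training-fold statistics.  Evaluation is repeated
stratified K-fold cross-validation (K ∈ {3,5,10} with 400/200/100
rounds by convention; tests use fewer rounds); random oversampling of
the minority class happens inside each training fold only, never on
test folds, to avoid leakage.  Cross-validated errors carry Wald
intervals p ∓ z_{α/2}√(p(1−p)/n), 80% by default.

## Synthetic study conditions

The feature-mode generator emulates the structure of a clinical cry
database: three health classes (Healthy, Neurological, Respiratory)
with 60/30/30 infants, two recordings each, split infant-disjointly
into ubm/adapt/test (40/30/30%).  Class-conditional differences are
mean shifts of magnitude δ per component (in per-dimension standard
deviations, along seeded random directions): δ = 1.15 for EXP and 0.85
for INSV, so the expiratory expert is the stronger one, as observed
with real cries.  Nuisance variation is layered as Gaussian random
effects on the component means — between-infant 0.75, between-recording
0.3, between-unit 0.4 — plus white feature noise (0.3); the infant
effect dominates file-level scores, which is what keeps synthetic
detection difficulty in a realistic range (EXP EER roughly 10–20%,
INSV 30–40% across seeds) rather than collapsing to zero error as
frame-level averaging otherwise would.  EXP units per recording are
1–8, INSV 0–4 (some recordings lack INSV entirely), trailing units may
be partial, and full units carry 120 frames — a deliberate desk-scale
reduction of the ~430 frames a real 3 s unit yields at 10 ms/30%
framing, keeping the full test suite and the acceptance script in the
minutes range.

The audio-mode generator renders cry-like waveforms by source-filter
synthesis: a Rosenberg-pulse glottal train at f₀ ≈ 450 Hz (newborn
phonation) with jitter/shimmer, formant resonators near 1.1 and
3.3 kHz, amplitude envelope, and additive noise at a set SNR; INSV
units are shorter, breathier and quieter.  Class identity offsets f₀.

What passing tests show — and do not.  The generator validates the
machinery: estimator correctness against brute-force oracles,
adaptation parameter recovery, the qualitative orderings (fusion not
worse than the best single expert; more cry units per file not worse
than fewer; BML-based methods not worse than MAP, judged within each
comparison's Monte-Carlo uncertainty).  With mean-shift-only class
differences and ample adaptation data, MAP and BML converge to nearly
the same models, so the BML-vs-MAP comparison resolves as a statistical
tie here; a strict advantage for BML is expected only in the
large-model/scarce-data regime of real corpora.  Nothing in the
synthetic world models infant physiology, real NICU noise statistics,
or segmentation error, so passing tests do not certify clinical
performance.

## Known limitations

- No automatic EXP/INSV segmentation: labels are inputs.
- No cepstral mean normalization, liftering, or T-/Z-norm variants
  beyond HNORM.
- The open-set "others" class is a rejection threshold on the winning
  pathology score (default calibration on adaptation-split non-target
  scores), not a trained model.
- Combination-rule fusion (sum/product/max) is out of scope; fusion is
  classification in the 2-D score plane.
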