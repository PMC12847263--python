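# Methods

## Signal model and decomposition

The pipeline treats one subject's ROI time series (T time points, R
regions, sampling interval Δt) as snapshots of a linear dynamical system
X′ ≈ AX, where X stacks time points 1…T−1 as columns and X′ the same
columns shifted one step. Exact DMD estimates the dominant eigenstructure
of A without forming it: with the thin SVD X = USV*, the reduced operator
Ã = U*X′VS⁻¹ is similarity-rescaled to Â = S^{−1/2}ÃS^{1/2} before
eigendecomposition, its eigenvectors are scaled back by S^{1/2}, and the
modes are mapped into region space as Φ = X′VS⁻¹W. The rescaling is the
"scaled modes" convention: it transfers the singular-value magnitudes into
the mode columns, so the squared column norm Pᵢ = ‖φᵢ‖² ranks modes by the
energy they carry in the data, analogous to a power spectrum. Frequencies
come from the principal branch of the eigenvalue logarithm,
fᵢ = |Im(log λᵢ)/Δt|/2π ∈ [0, 1/(2Δt)].

Numerical choices:

* No rank truncation by default — a full-rank T-point subject yields
  exactly T−1 modes. Singular values below 1e−12 × σ_max are dropped only
  to keep S⁻¹ finite.
* Eigendecomposition uses the rescaled Â (the similarity transform leaves
  eigenvalues unchanged); the eigendecomposition step, not an SVD, supplies
  Λ.
* Modes are ordered by ascending frequency, ties broken by descending
  amplitude, so outputs are reproducible run to run.
* Eigenvalues on the negative real axis alias to the Nyquist frequency and
  are logged; a zero eigenvalue (log undefined) raises.
* Reconstruction x(t) = Φ_s Λ_s^{t/Δt} b uses the Moore–Penrose
  pseudoinverse, b = Φ_s⁺x(0), because Φ is R×M and not square. When
  reconstructing from a mode subset, b is re-fit from the subset's
  pseudoinverse — the least-squares projection of x(0) onto the retained
  modes — rather than by zeroing entries of the full-mode b; re-projection
  is the only choice that makes the subset reconstruction a best
  approximation in its own span. The imaginary residual of the
  reconstruction is monitored and warned about when it is not negligible.
* Forecasting decomposes the first n_train points and evaluates the
  explicit model at later times; per-horizon RMSE above 1 (in signal
  units) is flagged as a failed forecast when summarising curves.

## Band filtering and features

Resting-state BOLD dynamics of interest concentrate in the infra-slow
0.01–0.1 Hz band; higher frequencies are dominated by cardiac/respiratory
physiology and very low frequencies by drift. Modes are filtered on the
closed interval [0.01, 0.1] Hz (the interval's openness is a convention;
the generator places no component on a boundary). For real-valued input the
spectrum is conjugate-closed, partners share a frequency and amplitude, so
pairs are kept or dropped together; both partners count as modes in all
averages.

The per-region feature is the mean over retained modes of
P_ij = |φ_ij|², the squared magnitude of mode i at region j (row sums of
the P_ij matrix reproduce Pᵢ exactly — an identity the tests assert at
1e−10). Sub-band features split [0.01, 0.1] Hz into k equal-width bands,
average P_ij within each band over that band's own mode count, and splice
the k blocks (ascending frequency) into an R·k vector. Interior band edges
are half-open [low, high), the last band closed at 0.1 Hz, so every mode is
counted exactly once; with band-specific denominators the count-weighted
recombination of per-band means reproduces the full-band feature
algebraically. A band containing no modes contributes a zero block with a
warning rather than an error, so sweeps over k never abort.

## Selection of abnormal regions

Features are z-scored (the L1 penalty is scale-sensitive) and regressed on
the 0/1 group label with the LASSO objective
(‖y − Xβ‖² + γ‖β‖₁)/2N, i.e. an effective coordinate-descent penalty of
γ/(2N); the default γ = 0.2 is a light penalty under which one fit keeps a
few dozen of several hundred features. Sparsity of the *final* answer comes
from stability, not shrinkage: each of n_repeats runs draws a fresh random
k-fold partition of subjects and fits on the training portion (a random
~90% subsample), and only features with nonzero coefficients in every run
survive. Chance-correlated noise features are selected erratically across
subsamples and are eliminated by the intersection, while genuinely
group-linked features persist. A magnitude floor of 1e−10 guards against
solver float dust when deciding "nonzero".

Each intersected feature is then tested with a two-sided label-permutation
test of |mean(patients) − mean(controls)|, using the add-one estimator
p = (#{permuted ≥ observed} + 1)/(B + 1); survivors at α = 0.05 are
reported as abnormal regions together with the mean coefficient β̄ across
runs, whose sign gives the direction of the deviation (positive = patient
group higher).

Two statistical caveats are properties of the procedure, not bugs. First,
the permutation test holds its nominal level for pre-specified features;
because the same cohort both selects the intersection and supplies the
test, p-values of intersected features inherit selection bias. The
intersection step is the practical false-positive control; the permutation
test is a secondary screen. Second, when several planted effects all
correlate with the label they also correlate with each other, and a heavy
penalty would arbitrarily prune some of them — the light-penalty +
intersection design deliberately avoids that failure mode.

## Classifier benchmark

Feature sets are compared with a linear SVM (C = 1.0) under shared
stratified rounds×folds cross-validation splits (default 3×10 → 30 metric
rows of accuracy, precision, recall, F1, specificity; patient = positive
class; standardization fitted on each training split). Variants: all
features; per-fold LASSO selection fitted on the training split only
(leakage-free); a fixed subset such as the repeated-LASSO intersection
(computed once on all data, hence optimistically biased — reported as
such); and a chance floor with permuted training labels. Metric
distributions are compared by an unpaired pooled permutation test of the
difference in means. Undefined metric ratios (a fold predicting one class)
are reported as 0 and flagged rather than raised.

## Mode connectivity (phiC)

Region j's "mode sequence" is row j of the (band-filtered) complex mode
matrix. Its similarity to region k is the real part of the uncentered
conjugate cosine, Re⟨row_j, conj(row_k)⟩ / (‖row_j‖‖row_k‖). Centering
across the mode index is deliberately omitted: the time course of region j
is Re Σᵢ φ_ji dᵢ(t) with temporal factors dᵢ(t) = bᵢλᵢ^{t/Δt} that have
approximately zero temporal mean and near-orthogonal waveforms, so the
time-domain Pearson correlation that defines FC maps onto the uncentered
inner product of mode rows — the mode index is not a sample and has no
mean to remove. On noiseless periodic cohorts this phiC matches FC at
cohort-mean off-diagonal r ≈ 0.993; a mode-centered variant degrades the
agreement to ≈ 0.966. Comparisons (Pearson r, RMSE) use strictly
upper-triangle entries only.

## Synthetic cohorts

The sinusoid generator emulates the statistical structure the analysis
assumes about preprocessed ROI BOLD: T = 140 samples at Δt = 2 s, R = 300
regions by default; oscillations at nine frequencies evenly spaced in
[0.015, 0.095] Hz (strictly inside the filter band) plus one out-of-band
component at 0.15 Hz, with phases i.i.d. uniform per
subject/region/frequency so subjects differ as real resting-state modes
do; additive Gaussian noise (sd 0.5) as the minimal residual model; and
per-region base amplitude 2.0, which concentrates ≥95% of values in
[−10, 10] as in typical preprocessed BOLD. Group effects multiply the
amplitude of in-band components at chosen (region, band) pairs by
1 + direction·relative_magnitude for patients only, so with zero noise the
planted amplitude ratio is exact. One cohort seed expands into per-subject
streams via seed-sequence spawning, making cohorts bit-reproducible and
parallel-safe.

The linear-system generator embeds a prescribed eigenvalue set (complex
values in conjugate pairs, |λ| ≤ 1) as a real block-diagonal system inside
R dimensions through a random orthogonal similarity, with per-subject
random initial states in the excited subspace; trajectories are exactly
linear, so recovered eigenvalues, reconstructions and forecasts have
closed-form truth. An optional RMS rescaling puts values on the BOLD-like
scale.

What these cohorts do *not* emulate: haemodynamic response convolution,
scanner drift, motion/physiological artifacts, spatial autocorrelation
between neighbouring parcels, or heavy-tailed noise. Passing tests
therefore demonstrate correctness of the algorithms and recoverability of
planted effects under the assumed signal model, not clinical validity on
real fMRI.

## Benchmark problem sizes

The recomputation script (`scripts/acceptance.py`) uses 10 noiseless
subjects for the phiC–FC agreement, 20 exact-linear subjects for
reconstruction, and 20 near-noiseless subjects (noise sd 0.01) for the
forecast curve, all at 140×300 and Δt = 2 s — cohort sizes at which the
cohort means are stable to well within the quantities' tolerances while a
full run stays fast on one CPU. Planted-recovery and benchmark-ordering
tests use 40 subjects per group, 100 selection repeats and B = 200
permutations, the same regime at which the selection procedure's behaviour
(full sensitivity, no false abnormal calls) is already asymptotic in our
sweeps.

## Known limitations

* DMD assumes (locally) linear dynamics; on real BOLD the model forecasts
  only a few steps beyond the decomposition window before the error curve
  grows.
* Abnormal-region p-values are post-selection (see above); treat them as a
  screen, not confirmatory inference.
* The fixed-subset SVM variant is optimistically biased by design, as the
  subset is chosen using all data; the per-fold-LASSO variant is the
  leakage-free comparison.
* The phiC definition for complex modes is a modelling choice (uncentered
  conjugate cosine); alternatives (centered complex correlation,
  magnitude correlation) do not reproduce FC.
* With R smaller than twice the number of excited frequencies the snapshot
  rank caps the recoverable modes and sub-bands can come out empty — the
  warnings make this visible.
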