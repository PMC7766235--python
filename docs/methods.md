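# Methods

## Problem

Mental-state classification from EEG (here: drowsy vs alert driving states,
binary labels with drowsy as the positive class) transfers poorly across
subjects: band-power feature distributions shift from head to head, so a
classifier trained on a pool of subjects degrades on a new one.  This
package implements an instance-weighted transfer scheme that "borrows" a
small labeled fraction of the new subject's data into the training pool and
uses boosting-style multiplicative reweighting to concentrate training on
the source samples that resemble the target subject.

## Feature pipeline

Raw multichannel signal (channels x samples, 200 Hz by default) is cut into
non-overlapping 0.5 s windows (100 samples at 200 Hz; trailing samples are
discarded).  Each window and channel gets a one-sided log10 power spectral
density on a 1 Hz grid: symmetric Hamming taper, zero-padding of the tapered
segment to `fs` points (the only transform length that lands bins exactly on
the integers 0..fs/2), periodogram scaled by the taper power with off-DC
bins doubled, and a floor of 1e-12 added before the log so silent bins stay
finite.  From the 101-point PSD the 27 values at the integer frequencies of
theta (4-7 Hz), alpha (8-13 Hz) and beta (14-30 Hz) are kept, and channels
are concatenated channel-major: `n_channels x 27` features per window
(61 channels -> 1647).  No per-window or per-channel power normalization is
applied before the log; scale differences are handled downstream by the
z-scoring step of the classifier.  A zero-phase order-4 Butterworth
band-pass (forward-backward) is provided as a pre-cleaning utility; its
design is a package choice, as is every constant in this paragraph that the
protocol leaves open (log base, floor, symmetric taper, discard rule).

## EasyTL core

*Intra-domain alignment.*  The source matrix is mapped to the target's
first- and second-order statistics:

    Xs' = (Xs - mean_s) (Cov_s + r I)^(-1/2) (Cov_t + r I)^(1/2) + mean_t

with ridge `r = 1` by default.  Mean matching is part of the alignment here,
not just covariance recoloring: log-power features carry per-subject
constant per-column offsets (channel gains enter the log additively), and a
residual mean gap `o` biases every nearest-center decision by the constant
`2 o . (c1 - c0)`, collapsing predictions onto one class.  The covariance
part alone cannot remove this.  Target statistics are computed from all
target-domain samples (borrowed plus unlabeled test), a transductive but
label-free use.

*Intra-domain programming.*  Class centers are the (sample-weighted) means
of the training pool after per-column z-scoring with the training pool's
statistics.  The annotation cost `D[c, j]` is the squared Euclidean (or
cosine) distance from center `c` to sample `j`.  The probability annotation
matrix `W` (classes x samples, column-stochastic) minimizes
`sum D[c,j] W[c,j]` subject to columns summing to one, `W >= 0`, and —
by default — at least unit total mass per class row, which prevents the
program from annotating a class out of existence.  With the class-mass
constraint the columns couple and the problem is solved as a sparse LP
(HiGHS); without it the minimizer is exactly the nearest-center indicator.
Labels are the per-column argmax, ties to the lowest class index.  For two
classes the constrained LP is a scalar transportation problem with a
closed-form optimum; the test suite uses that closed form as an independent
oracle.

## Instance-weighted boosting

Given source domain `T_sd` (all pooled training subjects, `n_s` samples)
and target domain (n_t samples), a stratified fraction
`m = round(lam * n_t)` of the target is borrowed into the training pool
`T = T_sd u T_td`; the remaining `l = n_t - m` samples `S` are the test
set and never influence the weights.  All weights start at 1.  Each of `N`
iterations: normalize weights to `p_t`; run one weighted EasyTL pass (the
LP is solved jointly over `T` and `S`, and the argmax labels are split
back); measure the weighted error `eps_t` on the borrowed samples only,
normalized by the borrowed pool's total weight and clipped into
[1e-10, 0.499] so that all `N` iterations always run and the final vote's
factors stay finite; set `beta_t = eps_t / (1 - eps_t)` and the constant
`beta = 1 / (1 + sqrt(2 ln(n_s) / N))`; multiply misclassified source
weights by `beta` (< 1) and misclassified borrowed weights by `1 / beta_t`
(> 1).  The final label of each test sample is the weighted vote of
iterations `ceil(N/2) .. N` with weights `-ln(beta_t)`, evaluated in log
space to avoid underflow; equality at the voting threshold counts as the
positive class.  `lam = 0` degenerates to a single plain EasyTL pass.
Defaults `lam = 0.3`, `N = 30` follow the protocol this implements.
Alignment runs once before the loop; the per-iteration step is programming
only.  Source-side hypotheses are recorded per iteration for diagnostics
(and to let the estimator replay the weight trajectory) but never enter the
error or the vote.

## Synthetic cohorts

The generator provides the study conditions in two modes.

*Feature mode* (default for cohort experiments): two Gaussian class
clusters in 16 dimensions with means `separation = 3` sd apart along a
fixed axis, per subject rotated by a random rotation of spectral angle
`subject_shift = 2` rad and translated by a random vector of length
`subject_shift * separation / 2`.  At these defaults cross-subject transfer
is genuinely hard for the aligned nearest-center classifier (~69% pooled
4-source accuracy on a held-out subject) while the boosted variant reaches
~78%, qualitatively mirroring the regime the method targets; at shift 0 all
subjects are i.i.d. and transfer is easy.  The separation is deliberately
small enough that within-subject accuracy has a ceiling below 100%; with
saturating separations every borrow ratio is equally easy and the
borrow-ratio trend flattens into noise.

*Raw mode*: per channel and class, two sinusoids per band at random integer
frequencies, amplitudes from the class band profile (drowsy: theta/alpha
elevated; alert: beta elevated), log-normal per-window amplitude jitter
(sd 0.3), white noise (sd 0.5), and log-normal per-subject channel gains
(sd 0.5 — typical gains within a factor 2-3, so band power shifts across
subjects without burying the oscillations under the noise floor).  This
mode exercises the complete signal -> PSD -> band-feature -> transfer path.

What the generator does *not* emulate: 1/f background spectra, artifacts
(EOG/EMG), nonstationarity within a session, channel covariance structure
from volume conduction.  Passing tests therefore show correct mechanics and
the intended qualitative behavior under controlled shift, not performance
on real EEG.

Problem sizes used by the test suite and the acceptance script — desk-scale
choices made once: cohorts of 5 subjects x 100 windows/class (8 channels in
raw mode), head-to-head and borrow-ratio studies over 20 independent cohort
draws with 4 pooled source subjects and one held-out target.

## Numerical choices

- LP solver: `scipy.optimize.linprog` (HiGHS), sparse constraints; solutions
  are clipped at 0 and columns renormalized to remove solver round-off;
  column sums are asserted to 1e-8 after every solve.
- Infeasible class-mass constraint (fewer samples than classes) falls back
  to nearest-center assignment with a warning.
- Covariance fractional powers via symmetric eigendecomposition with
  eigenvalues floored at 1e-12.
- Ties everywhere break toward the lowest class index; the voting threshold
  equality counts as class 1.
- Metrics with zero denominators return 0 with a warning; per-subject LOSO
  metrics are averaged unweighted.
- Determinism: the only randomness is the stratified borrow split, seeded;
  cohort generation is seeded per (cohort seed, subject id).

## Known limitations

- *Weight drift under class overlap.*  A borrowed sample that the
  nearest-center rule can never classify correctly gains a factor
  `1/beta_t` every round; over many iterations such samples dominate their
  class's weighted center and can drag it into the class-overlap region.
  In the no-shift separable regime borrowing is harmless (measured
  difference vs plain EasyTL: 0.05 percentage points), but with strong
  class overlap and nothing to adapt to, boosting can cost accuracy.  The
  half-window weighted vote mitigates but does not eliminate this.
- Binary labels only in the boosting core; the multi-class generalization
  of the final vote is out of scope.
- The annotation cost uses class centers; per-class distribution distances
  are a possible alternative the interface deliberately leaves one flag
  away (metric choice), but only centers are implemented.
- `EasyTLClassifier.predict` and the fitted `InstanceEasyTL.predict(X)` are
  transductive: alignment and standardization statistics depend on the
  batch/stored target; predictions on single samples inherit the stored
  statistics.
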