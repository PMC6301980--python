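# Methods

This note documents the models, defaults, and numerical choices behind
graspdyn, and what the synthetic generator does and does not emulate.

## Task model and synthetic sessions

A session is a sequence of trials of the delayed grasping task. Epoch
durations are drawn uniformly over the configured ranges — fixation
400–500 ms, cue 800 ms (fixed), memory 500–700 ms — and the hold lasts
1000 ms after the required force is reached. Uniform draws are the least
assumption given that only ranges are specified for these epochs. Force
bands are low 0–5 N, medium 5–9 N, high 9–12 N; the bands are contiguous,
so "entering the band" for the acquisition time (AT) means the first sample
at or above the band minimum.

Conditions are scheduled from a pool of 30 items (5 per condition):
successful draws are removed, failures stay, and one copy of each condition
is added whenever the pool drops below 25. This reproduces the property
that a condition failed more often is re-presented more often, while
keeping the next condition unpredictable.

Per-trial response times are truncated normals (at 0, or 80/50 ms for
RT/MT) with means and SDs taken from typical macaque performance on this
task: RT 268 ± 69 ms; MT 216 ± 32 ms (whole-hand) / 220 ± 42 ms
(precision); AT per condition ranging from 113 ± 230 ms (whole-hand low)
to 718 ± 360 ms (precision high). AT is clipped at zero: the force sensor
responds before the touch sensors, so low-force trials can satisfy their
band at the moment of touch. Only means and SDs are modeled; no claim is
made about the true shapes of these distributions.

The force trace is a logistic rise to a per-trial plateau drawn uniformly
inside the band (30–80 % of band width above the minimum), with the
crossing of the band minimum placed exactly at touch + AT and a time
constant `max(40 ms, AT/3)` so slower acquisitions rise more gradually. On
overshoot trials (per-condition probabilities defaulting to the 14–68 %
range observed in this task) a transient Gaussian bump exceeds the band
maximum during acquisition; force acquisition is then defined as the final
band entry, after which the trace stays in band for the full hold. Force
traces carry no measurement noise; degenerate configurations therefore
cross the band boundary at exactly the configured time, which the tests
exploit. A consequence is that early force traces are more regular than
real data, so small true differences between the medium and high force
levels in the first 100 ms after touch can reach significance where real
sessions may not show them.

Trials fail with configurable probabilities (default 10 % eye-fixation
errors before go, 3 % execution errors, 2 % double touches). Fixation
failures truncate the event sequence at go; both kinds leave the drawn
condition in the scheduler pool.

### Planted latent structure

Firing rates are built as baseline + mixing · latents, rectified at zero,
with one latent per marginalization: a condition-independent reach/grasp
profile peaking at touch; a force profile maximal in the hold epoch with
per-level coefficients (−1.1, 0.1, 1.0) (zero-mean across levels, so the
latent lies purely in the force marginalization); a grip profile peaking at
touch with coefficients (−1, +1); and an interaction profile with doubly
centered coefficients. Latent amplitudes are solved so the pre-rectification
variance shares equal the requested targets exactly (defaults
0.70/0.15/0.10/0.05); the recorded ground truth is the share of the
rectified tensor, which differs by ≲0.1 percentage points at the default
modulation (RMS 5 spikes/s on baselines of 15–30 spikes/s, clipping
fraction ≈ 0.1 %). At much larger amplitudes rectification distorts the
planted shares; the ground-truth tensor, not the targets, is then the
reference.

Latent time profiles live on the composite timeline and are mapped into
each trial's real time per alignment window, linearly blended across
window gaps and overlaps. Spikes are inhomogeneous Bernoulli/Poisson draws
at 1 ms. EMG shares the condition-independent and force latents through
positive muscle weights, is gated off before movement, and by default
amplitude-modulates a broadband noise carrier so the full band-pass /
rectify / smooth / normalize chain is exercised; the noiseless envelope is
available for diagnostics. The default session is 100 units and 500 trials
— smaller than a typical recorded session (~640 trials) to keep simulation
and test time proportionate; all statistics scale with these counts in the
standard ways.

## Signal conditioning

All filters are zero-phase. The Butterworth stages (EMG band-pass 25–250 Hz
order 6; broadband low-pass 5000 Hz order 4) run forward–backward, which
doubles the effective order; the stated orders are the design orders. The
Gaussian kernel is truncated at 2.5 σ and renormalized to unit sum so
constants are preserved. The median high-pass window is converted to the
nearest odd sample count (3.33 ms at 30 kHz → 99 samples); edges use
shrinking windows rather than padding. PCA artifact cancellation
normalizes channels to unit variance, removes principal dimensions whose
loading vectors have no coefficient above 0.36 in magnitude (a dimension
spread across ≥ ~8 channels of a 32-channel array), and restores the
original scale; dimensions with any loading above threshold are retained so
no single channel's signal can be eliminated. This identification fails
only in the degenerate case of an exactly isotropic spectrum, where
principal axes are arbitrary.

## Composite timeline and rates

Spike trains are binned at 1 ms, convolved with the unit-sum Gaussian
(σ = 50 ms), scaled to spikes/s, and sampled at the 10-ms bin centers of
three alignment windows (cue onset −400..+1300; touch −500..+500; reward
−1000..+200), giving 390 bins. Each window is extended by the kernel
support before convolution and cropped, so bins inside the window are free
of boundary bias. Center-sampling (decimation) is used instead of within-bin
means; with σ = 50 ms the difference is far below trial noise and the
semantics are exact.

When a condition's median AT is below 500 ms, the span from touch + 500 ms
to reward − (median AT + 500) ms appears in both the touch- and
reward-aligned segments; it is masked for display and replaced by linear
interpolation between its boundary bins for statistics. Interpolation
method is a package choice (linear), applied per condition using that
condition's median AT over retained trials.

## Cluster-based permutation test

Per unit: two-way ANOVA (grip × force with interaction) per 10-ms bin,
using Type II sums of squares because trial counts per cell are unequal
after exclusions. Bins with p < 0.01 (equivalently F above the fixed
critical value for the effect's degrees of freedom) form clusters of
adjacent bins; each cluster's F-values are summed. The null distribution
per effect takes, from each of 1000 label permutations, the largest summed
F of that effect; an observed cluster is significant when its sum exceeds
the 99th-percentile threshold, computed as the ⌈n·0.99⌉-th order statistic
with ties resolved upward (conservative). Permutations are shared across
the three effects within a unit for reproducibility and speed; the three
null distributions are still built separately per effect. Clusters never
span the cue→touch segment boundary (adjacency across a cut in real time
is meaningless); the touch→reward boundary counts as adjacent when the
overlap span was interpolated. Under label exchangeability the per-effect
family-wise rejection probability is ~11/1001 ≈ 0.011 by the rank argument,
which the calibration suite verifies empirically.

The implementation vectorizes the ANOVA over bins and permutations via
per-cell sums (every model in the 2×3 layout fits cell means, so all SSE
terms are quadratic forms in six sums), one GEMM per unit; it is verified
bin-by-bin against statsmodels' `anova_lm` (Type II) in the tests.

## Demixed PCA

Fitting uses the trial-averaged tensor, per-unit grand mean removed. For
each combined marginalization X_φ the reduced-rank ridge problem
min ‖X_φ − A X‖² + μ‖A‖² with rank(A) ≤ q is solved in closed form:
A = X_φ Xᵀ (X Xᵀ + μI)⁻¹ followed by projection onto the leading left
singular space of A X (pseudo-inverse at μ = 0 for rank-deficient data).
The ridge parameter is λ·‖X‖ squared, with λ selected on a grid (0 plus 10
log-spaced values 1e−7..10^−2.5) by 10 rounds of held-out-trial
reconstruction: one random trial per unit and condition forms the test
tensor, the rest the training average. Components are ordered by explained
variance (‖d fᵀX‖²/‖X‖²), at most 30 kept.

Raw marginalization shares of a finite-trial average are inflated by
trial-to-trial noise. The reported signal shares subtract a split-half
noise floor: half the difference of two half-means has exactly the noise
covariance of the full mean, so marginalizing it estimates the noise
sums-of-squares per marginalization without assuming noise that is
condition-independent or white in time (Poisson noise is neither). The
floor is averaged over 10 random splits; corrected shares are clipped at
zero. Raw shares remain available.

Decoding holds out one trial per unit and condition (pseudo-single-trial
assembly: one same-condition trial sampled per unit; simultaneous
recordings pass through unchanged), refits the factor's leading decoder
axis on the training trials only — held-out data never touches the axis,
otherwise accuracy on null data sits above chance — and classifies the
held-out projection by the nearest training class mean per bin, averaged
over 100 iterations. Chance comes from 100 runs with per-unit
label-shuffled trials; a bin is significant when the actual accuracy
exceeds all shuffles, and reported intervals require ≥10 consecutive
significant bins. Note that shuffling the trials of strongly structured
data leaves residual decodable signal through the finite-sample composition
of the shuffled cells; the chance distribution absorbs this, but "shuffled
accuracy" on such data is legitimately above naive chance. The
condition-independent marginalization has no labels and is not decoded.
EMG is never fed to dPCA (too few muscles for a population decomposition);
EMG uses the marginalization algebra only.

## Neural–EMG correlation

Muscles are marginalized individually and the marginalizations averaged
(the alternative — average the muscles first — differs only through the
nonlinearity of neither step, i.e. not at all for these linear averages,
but the order is fixed and documented). The time shift is chosen on a
−500..+500 ms grid in 10-ms steps (the analysis bin width; finer shifts
would be interpolation artifacts) to maximize R² between the reference
condition-independent component (largest by default; configurable to the
second-largest for areas where the largest is muscle-unrelated) and the
EMG condition-independent marginalization. That single shift applies to
all factor/component pairs; per factor, the per-condition time courses are
concatenated (3 segments for force, 2 for grip) before one squared Pearson
correlation. Shifted series are cropped to the overlap (masked, not
zero-padded, which would bias R² toward zero asymmetrically) and require
≥50 % overlap. Positive shift means the neural signal precedes the muscle.

## Pipeline

Stage seeds derive from SHA-256 of (global seed, stage name), so stages can
be re-run independently and the whole pipeline is byte-reproducible from
one seed. Outputs are TSV (tables), HDF5 (signals, tensors; sampling-rate
attributes), JSON (ground truth, reports). A thin click CLI (`graspdyn
simulate|behavior|validate|run`) wraps the library for shell use.

## Problem sizes and limitations

Calibration suites use 1000 null units (error control), 200 units (power),
100 units × 20 trials/condition (dPCA recovery), and 40 seeds (shift
recovery); these sizes put Monte-Carlo error comfortably below the margins
being tested while keeping runs to minutes. Known limitations: the
generator has no biomechanics (force dynamics are a parametric
convenience), no eye movements, no inter-unit noise correlations, and no
session-to-session drift; rectification distorts planted shares at large
amplitudes; the cluster test assumes exchangeable trials (no slow
nonstationarity); the split-half noise floor assumes trials are
identically distributed within a condition. Passing tests demonstrate
correctness of the estimators under these conditions, not robustness to
every property of real recordings.
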