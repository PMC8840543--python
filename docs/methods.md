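# Methods

## Problem and model

Accelerometer-based activity recognition extracts window-level statistics
from wrist-worn tri-axial recordings and classifies the activity being
performed.  The same statistics predict soft identifiers — gender and age
group — so a data release that supports activity recognition also leaks
identity traits.  `privhar` treats de-identification as feature weighting:
a genome **v** ∈ [0, 1]⁶² multiplies the 62 features element-wise, and a
many-objective evolutionary search minimises the vector

(gender accuracy, age accuracy, 1 − action accuracy)

measured by a wrapper: three random-forest classifiers trained under
k-fold cross-validation on the weighted features.  The Pareto front of
weight vectors exposes the privacy/utility trade-off; a single "best"
member is picked for reporting.

## Pipeline parameters

| stage | parameter | default | meaning |
|---|---|---|---|
| filtering | Butterworth order / cutoff | 4 / 15 Hz | low-pass, causal single-pass (a `zero_phase` flag enables forward–backward) |
| | median order | 3 | despiking, edge replication |
| windowing | window / overlap | 160 samples / 20% | 5 s at 32 Hz; stride 128 (ties in fractional strides round down) |
| inductor | trees / folds | 90 / 10 | scikit-learn `RandomForestClassifier`, stratified folds computed once per run and reused for every candidate |
| optimizer | population / offspring | 50 / 10 | steady-state-like: only offspring are evaluated per generation (canonical generational mode behind a flag) |
| | M / p | 3 / 8 | 45 Das–Dennis directions; configurations where C(M+p−1, p) exceeds the population are refused |
| | SBX η / prob | 30 / 1.0 | per-gene exchange probability 0.5 |
| | PM η / prob | 20 / 1/62 | bounded polynomial mutation |
| | generations | 50 | fixed-count termination |
| genome | bounds / init | [0, 1] / uniform | log-uniform initialization available (`init="loguniform"`); all-ones seeding behind a flag |

The sample rate is configurable and defaults to 32 Hz, consistent with
5 s = 160 samples.  With that rate the default 15 Hz cutoff sits at 0.94
of Nyquist and is nearly all-pass; it is kept as specified and
configurable.

## Estimator conventions

Where the literature leaves the estimator open we fix: population σ
(divide by N); skewness/kurtosis as standardized moments with kurtosis
reported as excess; lag-1 autocorrelation of the SMV; percentiles by
linear interpolation; peak count = strict local maxima of the SMV with
prominence above the window's SMV σ (threshold configurable); SMA =
mean(|x|+|y|+|z|); energy = mean(SMV²); spectrum = one-sided FFT magnitude
scaled 2/N with the DC bin excluded and no taper; spectral entropy on the
power spectrum normalised to sum 1, natural log.  Degenerate zero-variance
windows map correlation, CV, skewness, kurtosis and autocorrelation to 0,
so feature vectors are always finite.  Every statistic is verified against
an independent direct-formula oracle (dense-DFT, sort-and-interpolate,
manual prominence walking) to 1e-9 relative tolerance.

## Weight quantization (making the wrapper weight-sensitive)

Multiplying a feature by a positive constant is order-preserving, so
tree-based classifiers are *invariant* to positive weights: without
intervention the genome would only matter at exactly zero.  The inductor
therefore offers a post-weighting quantization step (off by default): each
weighted feature column is rounded to a grid of step `q·σ_f` centred on the
column mean, where σ_f is the unweighted column's population standard
deviation.  A feature at weight w then retains roughly `4w/q`
distinguishable levels across its ±2σ span and collapses to a constant
once its weighted spread fits inside one cell — weights become
monotonically informative.  The grid is tied to each feature's own scale
because several features (e.g. the coefficients of variation) are
unbounded ratios that an absolute grid would never coarsen, and it is
centred so that a near-dead feature cannot survive as a spurious binary
split when a cell boundary happens to cross its (tiny) range.

## Synthetic cohort generator

The generator emulates a cohort of participants, balanced genders,
age bins filled round-robin in M/F pairs (so age never confounds gender),
performing repetitions of up to 24 ADL classes; defaults follow the
conditions of the real recording campaign it stands in for (52 subjects,
24 activities, 5 repetitions, ±2 g range, 0.015 g resolution, 32 Hz,
30 s sequences).  Each sequence is

* **activity**: per-activity posture offset per axis (gravity
  orientation), a fundamental oscillation at a per-activity base frequency
  with per-axis amplitudes, fixed inter-axis phase lags and a first
  harmonic, plus broadband low-pass motion texture (unit-variance,
  per-axis independent) — all scaled by `trait_effect_sizes.activity`;
* **gender**: a multiplicative shift of the oscillation rate (log gap
  `trait_effect_sizes.gender` on the fundamental, per-repetition jitter) —
  gender surfaces in rate-sensitive features (peak count, autocorrelation,
  spectral centroid) and nowhere in amplitude;
* **age**: motion smoothing — the texture bandwidth shrinks geometrically
  with the age bin (6 Hz down towards 1.2 Hz) — plus a narrowband 8–12 Hz
  tremor whose amplitude grows with the bin, both scaled by
  `trait_effect_sizes.age`;
* sensor model: additive Gaussian noise, clipping to ±range, quantization
  to the resolution.

Design rationale: the trait signatures are deliberately *narrow* spectral
perturbations riding on a trait-free broadband texture.  If a trait
instead scaled the overall amplitude it would leak into every
variance-sensitive feature; a redundant random forest then holds its
accuracy until nearly all of those features are destroyed, and the wrapper
objective becomes a step function that no evolutionary budget can descend.
Concentrating each trait in a limited, distinct channel (gender → rate,
age → bandwidth) gives the optimizer a navigable landscape and mirrors the
empirical observation on real recordings that frequency-domain features
are the strongest identity leak.  Effect sizes are free parameters of the
generator, chosen so that baseline trait accuracies sit clearly above
chance while near-chance concealment remains achievable; they are not
calibrated to any real dataset.

With all three effect sizes zero the output is pure quantized noise and
all classifiers sit at chance; with the default activity effect, action
recognition on held-out subjects is near-perfect.  Generation is
bit-reproducible from the seed.

What the generator does **not** model: biomechanical realism, within-class
movement diversity, device orientation drift, per-subject idiosyncrasy
beyond an optional motion-scale multiplier (default off), or the
instance-count imbalance of real campaigns.  Passing tests on this
benchmark therefore demonstrate that the pipeline and optimizer work as
designed — not that equal drops would be obtained on real recordings.

## Evaluation design

Cross-validation is window-level by default, matching how sample counts
are usually reported.  The shipped benchmark instead uses
**subject-grouped folds**: overlapping windows from one sequence carry the
sequence's random phases and jitters, so window-level folds let the forest
re-identify the sequence (and hence its subject's traits) by memorisation.
Grouped folds measure what de-identification is actually about —
generalisation of trait inference to unseen people.  Fold assignment is
computed once per run and reused for every candidate so that objective
differences between genomes are not confounded by fold noise; classifier
seeds derive deterministically from (run seed, candidate index, fold,
task), which makes parallel evaluation bit-identical to sequential.

## The reduced benchmark

The shipped de-identification benchmark uses 12 subjects (6 M / 6 F, 3 age
bins, 4 subjects per bin), 6 activities, 3 repetitions (1512 windows),
trait effects gender 0.35 / age 0.3, 90-tree forests with grouped 3-fold
CV, quantization step q = 0.5, and NSGA-III with population 12, p = 3 (10
directions), 10 generations of 10 offspring.  Sizes were chosen so a full
run completes in a few minutes on one CPU.  Two optimizer settings differ
from the package defaults, as recorded configurable decisions: genomes are
initialised log-uniformly over [10⁻³, 1] (weights are scale factors, and
the quantized wrapper's responsive regime spans roughly two decades below
1), and the mutation rate is raised to 0.2 with SBX η = 15 (a
100-evaluation budget needs coordinated multi-gene moves that the
canonical 1-gene-per-child mutation cannot produce).

## Best-individual rule

The reported "best" solution minimises the Chebyshev (max-coordinate)
distance to the front's ideal point after per-objective min–max
normalization over the front, ties broken by lowest index.  The rule is
pluggable; any front member is a valid operating point on the
privacy/utility trade-off.

## Known limitations

* Quantization-mediated weight sensitivity is a modelling choice; other
  inducers (distance- or margin-based) would respond to weights directly.
* With few subjects per fold, trait accuracies on grouped folds have
  subject-level variance; the benchmark's fixed seed makes runs
  reproducible, but a different cohort draw shifts baselines by a few
  points, and under the 100-evaluation search budget the achieved
  concealment varies across seeds as well (the drops can fall below ten
  points for some draws).  Larger cohorts and longer runs tighten both.
* The steady-state evolution (10 offspring) explores slowly; large
  de-identification studies should raise the generation count or use the
  canonical generational mode.
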