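# Methods

This note records the modeling conventions, defaults and known limitations
of the package; the README covers the overall framework.

## Data model and encoding

A record is one siRNA compound: an id, a target gene, the 20-nt mRNA
target-site sequence over {A, C, G, U} (positions t1..t20, pairing with
guide positions g1..g20; RISC cleaves between t10 and t11), and its
efficacy as percent reporter expression remaining (lower = more
effective), optionally with replicate measurements.  T is accepted on
input and silently mapped to U because published external siRNA sets use
DNA overhang conventions.  The replicate-mean consistency tolerance is an
absolute 0.5 percentage points, since printed efficacies are rounded.
Sequences are one-hot encoded position by position in the fixed base order
A, U, C, G (80 features); that column order is canonical for every weight
matrix the package emits.  The package takes the target-site string as
already written in t1→t20 register; how that register maps onto genomic
coordinates is left to the caller, and the transcript scanner isolates the
choice in one place (windows are emitted 5'→3' and encoded as-is).

## Thresholds and labels

Candidate thresholds are interior equal-count boundaries: threshold k is
the largest observed value v with at most k·n/n_groups values ≤ v (lower
empirical quantile), so thresholds sit at observed data values.  Ties
across boundaries raise a degeneracy error rather than silently collapsing
groups.  Labels are: efficacy ≤ h1 → effective, efficacy > h2 →
ineffective, otherwise undefined (excluded from model development); with
h1 = h2 nothing is undefined.  Threshold values are rounded to integer
percent for display only — classification always uses the exact values.

## Splitting and cross-validation

The stratified holdout split draws without replacement per class with a
seeded generator; the training set holds round(0.75·n) records, allocated
per class by largest remainder, so per-class proportions are preserved
within one record.  The K-fold plan (K = 10) shuffles and splits each
class independently into K near-equal chunks, then pairs the larger chunks
of one class with the smaller chunks of the other, so fold sizes *and*
per-fold class counts each differ by at most one.  Records are pre-sorted
by id before any seeded step, making every result independent of input
row order.  Threshold pairs whose classes are too small to split or fold
(fewer than 2 per class, a training class smaller than K, or a holdout set
missing a class) are marked degenerate and skipped with a logged reason —
on small datasets stringent pairs legitimately produce empty cells, and
aborting the sweep for them would hide the rest of the grid.

## Classifiers

The forest uses scikit-learn's RandomForestClassifier with 200 trees,
maximum depth 3 and at least one sample per leaf; these are fixed
framework constants, not tuned hyperparameters.  Confidence is
`predict_proba` for the effective class (the average over trees of the
leaf class frequencies, which equals the fraction of trees voting positive
when leaves are pure).  The linear classifier's weights are the per
position-base frequency difference between effective and ineffective
training records; a sequence's raw score is the inner product of its
one-hot vector with the flattened weights.  Because the framework's curves
need a [0, 1] confidence, raw linear scores are min-max mapped over the
training-set scores and clipped for out-of-range probes; this affects only
the margin intercept, never the ranking.  A degenerate training set whose
scores are all equal maps every probe to 0.5 (no ranking information
exists).  Binary calls use confidence > margin with the margin fixed at
0.5; a score exactly at the margin is called negative — conservative for
siRNA design, where a false positive (a synthesized dud) is the costly
error.

## Evaluation

The precision-recall curve has one point per distinct score threshold in
descending order, a left endpoint at (recall 0, precision 1) for the
zero-positive prediction, and the all-positive endpoint at (recall 1,
precision = prevalence).  AUCPR is the step sum Σ (r_i − r_{i−1})·p_i
(the average-precision convention); trapezoidal interpolation is avoided
because linear interpolation between PR points is known to be optimistic.
P_R=1 is the precision of the all-positive prediction, i.e. the
positive-class prevalence — exactly the right endpoint of the curve — so
AUCPR_adj = AUCPR − P_R=1 is 0 for uninformative scores at any prevalence
(both terms equal the prevalence) and may be negative for
worse-than-baseline rankers.  ROC AUC (ties counted half) is computed for
comparison only.  Cross-validation aggregates the K fold curves by
vertical averaging on a shared 101-point recall grid with step
interpolation; the CV-stage AUCPR integrates the averaged curve, P_R=1 is
the mean fold prevalence, ROC AUC is the mean fold ROC AUC, and the
contingency table pools the folds at the 0.5 margin.  Stage-wise 0–100
normalization of AUCPR_adj is one min-max call over all non-degenerate
pairs of that stage (CV and holdout separately, never across stages);
constant input maps to 0.

## Attribution

The proxy extraction needs only classification outputs, so it applies to
any model family.  Records of the evaluation set are binned into TP, TN,
FP, FN at the 0.5 margin; each group's one-hot vectors are averaged
(unweighted by group size — an optional size-weighted reading would
instead compute a covariance-like quantity and is not what the method
describes); each average is signed by the class the group represents
(effective +, ineffective −) and the incorrect groups are negated, giving
TP +, FN +, TN −, FP −; the four signed vectors are summed and reshaped
to 20×4.  An empty group contributes the zero vector, the neutral element
of the sum.  With these signs a model with no errors reduces exactly to
mean(effective) − mean(ineffective), which for the linear family *is* the
direct weight matrix — the basis of the direct-versus-proxy consistency
check.  The alternative "correctness" signing (TP +, TN +, FP −, FN −) is
kept as a sensitivity variant: it contrasts correctly with incorrectly
classified records and carries no class direction, because conditioning
both positive and negative terms on the prediction cancels the class
signal; on planted-signal synthetic data its sign agreement with the
ground truth is at chance level, which is why it is not the default.
Evaluation records default to the training set (the records used in model
development); a switch allows holdout or all labeled records.
Normalization scales the matrix so max |w| = 100 (sign-preserving, an
all-zero matrix passes through) and zeroes entries with |w| < 20 to
suppress low-weight noise; it is idempotent.  The AU−GC trend is the
per-position (A+U) − (G+C) weight sum, a proxy for local duplex
thermodynamic stability.

## Synthetic data generator

The generator emulates the reference study conditions: 356 records over 17
genes (the per-gene count follows from the totals), efficacies clipped to
[4, 120] and calibrated to mean 44, three replicates per record.  It does
not reproduce the mild right skew of real reporter data (the latent scale
is standardized and affinely mapped, so the median tracks the mean rather
than sitting a few points below it), nor real transcript composition or
off-target structure — it exists to exercise the framework, not to fool a
biologist.  Defaults, chosen once as realistic study conditions:

- `efficacy_scale = 27` (pre-clipping SD): puts the 4–120 bounds at about
  ±1.5–2.8 SD from the mean, matching a screen whose observed range is
  4–120 around a mean of 44.
- `effect_strength = 12`, `noise_sd = 15`, `gene_effect_sd = 5`: the
  planted sequence term then explains roughly half the latent variance —
  a moderate, recoverable signal; the per-gene offsets give CV folds
  realistic between-gene structure.  The gene-effect scale is a
  convention, not an observed quantity.
- `effect_sparsity = 0.25`: ⌈0.25·80⌉ = 20 nonzero planted entries with
  magnitudes uniform in [0.4, 1.0]·strength and random signs.
- replicate noise: per-record SD drawn half-normal with scale 4.7 and
  capped at 16, giving a mean absolute replicate error of ≈ 3% and
  per-record SDs up to 16%; replicates are clipped to the efficacy bounds
  and their mean is stored as the record's efficacy, so generated records
  satisfy the core validation invariants by construction.
- `gc_content = 0.4`: screens of this type favor low-GC sites.
- interactions (off by default): 8 pairwise base conjunctions with
  coefficients of magnitude ≈ 18–30, used to plant a nonlinear signal the
  depth-3 forest can represent but a positional linear model cannot.

Planted weights act on *efficacy* (expression remaining): a positive
planted entry makes carriers less effective.  Extracted weight matrices
point the other way (positive = favored among effective), so parameter-
recovery checks compare extracted signs against the negated planted signs.

## Determinism and problem sizes

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawn keys (one stream per family × pair for
splitting, folding and forest seeding), so a sweep is reproducible to the
byte and independent of record order.  The test suite and the acceptance
script run everything at the defaults above: the full 45-pair forest sweep
on 356 records takes on the order of two minutes on one CPU; unit and
property tests use reduced sizes (120-record datasets, 12–40-record
partitioning instances, n ≤ 30 metric oracles) chosen so each check still
exercises the property it names.

## Known limitations

- The linear family's confidence mapping (min-max) is a package
  convention; only its ranking, not its calibration, is meaningful.
- AUCPR_adj comparisons across pairs inherit holdout sets as small as a
  few dozen records under stringent pairs; single-record changes move the
  metric visibly, which is inherent to the problem size, not the metric.
- Proxy attribution is dataset-level only (no per-record attributions) and
  may fail to separate correlated position-base features.
- The generator's gene effects are exchangeable offsets; real per-gene
  efficacy structure (target abundance, mRNA structure) is out of scope.
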