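# Methods

## Data model and transformations

A dataset is a rectangular table of text cells with declared attribute
kinds (categorical or numeric) and per-record suppression flags. All
transformations operate on this representation:

* **Generalization** replaces each quasi-identifier cell by its
  representation at a chosen level of the attribute's hierarchy
  (full-domain: one level per attribute for the whole column).
  Hierarchies are validated on construction: unique leaves, rectangular
  rows, and *coarsening* — two leaves sharing a value at level ℓ share a
  value at every coarser level (checked as functionality of each
  level-to-next-level mapping).
* **Categorization** of numeric attributes is a hierarchy built from an
  interval specification: strictly increasing cut points define
  half-open level-1 intervals `[cᵢ, cᵢ₊₁)`; each further level merges
  `merge_factor` adjacent intervals until one interval covers the domain.
  Values not present in the sampled leaf table are generalized
  analytically by interval membership; values outside the declared
  domain are an error during anonymization.
* **Record suppression** flags rows; they are excluded from equivalence
  classes and classifier training but retained (fully starred) in
  written output so record counts stay auditable.
* **Random sampling** keeps each record independently with probability β
  (one explicit seed, recorded in the result metadata).
* **Aggregation** replaces a numeric attribute by its per-class mean or
  median, rendered at 6 significant digits; **cell/attribute
  suppression** replaces cells by `*`.

Unknown categorical values are an error during anonymization but map to
the hierarchy's top level during evaluation-time preprocessing, so a
deployed model never fails on unseen input. Already-generalized labels
are accepted at levels at or above their own, making preprocessing
idempotent. Missing input cells become the ordinary category `NA`
(categorical); missing numeric cells are an error unless the attribute
is excluded.

## Privacy criteria

**k-anonymity** requires every equivalence class over the transformed
quasi-identifiers to have at least k records; the maximum per-record
re-identification risk is 1/(minimum class size), and a partition is
k-anonymous iff that risk is ≤ 1/k.

**Sampling-based (ε, δ)-differential privacy.** Bernoulli sampling with
probability β, followed by *data-independent* transformation and
suppression of every class smaller than a threshold k, satisfies
(ε, δ)-DP. The tight sampling budget is ε = −ln(1 − β); conversely
β = 1 − e^(−ε) is the largest admissible sampling probability at budget
ε. The residual is

δ(k, β, ε) = max over n ≥ n_m of P[Binomial(n, β) > γn],
γ = (e^ε − 1 + β)/e^ε,  n_m = ⌈k/γ⌉ − 1.

The scan over class sizes n stops once a Chernoff bound
exp(−n·KL(γ‖β)) on the tail falls a factor 10¹⁵ below the running
maximum (γ > β holds whenever ε ≥ −ln(1 − β), so the tail decays
geometrically; the truncation is validated against direct maximization
up to n = 10⁴ in the test suite). Given a requested (ε, δ) and an
optional search budget ε_s < ε, the derived parameters are
β = 1 − e^(−(ε − ε_s)) and the smallest k with δ(k, β, ε − ε_s) ≤ δ,
found by bisection (non-increasing in k); thresholds above 10⁵ are
reported as infeasible. Worked example: β = 3/5 gives ε ≈ 0.92, and at
k = 3, γ = 0.84, the maximizing class size is n = 3 with tail
0.6³ = 0.216 ≈ 0.22.

**Game-theoretic profitability.** Attacking a record in a class of size
s has expected adversary payoff G/s − c. The implemented decision rule is
the "no-attack" variant: a release is safe iff that payoff is
non-positive for every class, equivalently iff the minimum class size is
at least ⌈G/c⌉. The publisher's payoff (benefit b per published record
minus expected loss G/s per record in profitable classes) is reported
alongside. When c = 0 and G > 0 no finite class size protects; the
effective threshold is infinite and only total suppression satisfies the
criterion (documented edge case).

## Utility model

The penalty of a transformed, post-suppression dataset for a target t is

penalty(t) = #suppressed + Σ_classes (size − majority count of t),

summed over all configured targets (summation rather than averaging —
equivalent orderings at fixed target count). Majority ties do not affect
the count; where a majority label is reported, ties break by first
appearance in the data for determinism. The normalized score divides by
records × targets, so 0 means every class target-pure with nothing
suppressed.

The differential-privacy score of a candidate scheme is the dual form
*score = #unsuppressed − Σ_targets Σ_classes (size − majority)*, which is
0 for a fully suppressed output, n for a perfectly pure unsuppressed one,
and satisfies score + penalty = n for a single target. Its sensitivity
constant defaults to 1 and is validated empirically by neighboring-
dataset sweeps in the test suite rather than asserted from theory.
Penalties and scores are always computed on the post-suppression
partition of each candidate, so privacy and utility see the same data.

## Search

The anonymizer enumerates the full generalization lattice (all
Π(Lᵢ+1) level combinations, total level ascending, lexicographic within
ties; refusal above 10⁶ nodes), and for each node: transforms, suppresses
classes below the criterion's effective class-size threshold (k, or
⌈G/c⌉ for the game model) up to the suppression limit (default 100%),
checks the criterion, and keeps the satisfying node with minimal
penalty. Ties resolve to the earliest node in enumeration order, i.e.
less total generalization. There is no predictive pruning — evaluation
is exhaustive, with per-level column transforms computed once and
partitions formed on integer codes — so the optimizer can be (and is)
checked against a naive re-evaluation of every node through the public
reference operations. If no node satisfies the criterion, the error
lists the closest candidates by required suppression fraction.

Fully generalizing an attribute to a single value removes it as a
feature; such attributes are reported as *removed* (automated
dimensionality reduction).

Under differential privacy the pipeline is: derive (β, k); sample;
choose the scheme — the configured fixed scheme in data-independent mode
(the default, ε_s = 0), or an exponential-mechanism draw with weights
exp(ε_s·score/(2·sensitivity)) computed in log space via the Gumbel-max
trick in search mode; generalize; suppress all classes below k with no
limit. All derived parameters (β, k, γ, seeds) are echoed in the result
metadata.

## Evaluation protocol

Record indices of the *original* dataset are split into stratified folds
(default 10; shuffled with a recorded seed; an error is raised if some
class has fewer records than folds). Per fold, three models are fitted:
the chosen classifier on the anonymized rows of the training folds
(fully suppressed rows dropped), the same classifier on the unmodified
training folds, and the zero-rule baseline on the unmodified training
folds. All three predict the held-out original records; for the
anonymized-trained model those records are first preprocessed with the
same hierarchies and levels used for training (only generalized or
categorized attributes need mapping — suppression, sampling and
aggregation preserve the value domain). Sampling-based releases are not
row-aligned with the input, so there the anonymized-side model is
trained once on the whole release; it never sees raw records, so no raw
train/test leakage arises. If an anonymized training fold retains fewer
than two target classes, the anonymized-side model falls back to the
class priors of the remaining rows (uniform if none), so heavily
suppressed releases evaluate to baseline-level performance instead of
failing.

Pooled out-of-fold predictions yield the metrics. Features are one-hot
encoded per observed category (generalized labels are opaque symbols);
numeric features pass through, mean-imputed where unparseable, and are
standardized for logistic regression only. ROC curves use a full
threshold sweep; AUC is the trapezoid area, which equals the
positive-over-negative rank statistic with ties counted ½. The
multiclass Brier score uses the full-vector convention (range [0, 2];
the binary convention would halve it). The relative AUC denominator uses
the *empirically measured* zero-rule AUC rather than a hard-coded 0.5:
within a fold the zero-rule scores are constant (AUC ½ by the tie
convention), but pooling folds with slightly different class priors can
move it a few hundredths off 0.5. This choice is visible in the reports
and means printed relative values elsewhere computed against a fixed 0.5
baseline will differ slightly. Relative AUC is clipped below at a
configurable floor (default 0%) for reporting; the Brier skill score
1 − Brier_anon/Brier_orig is unbounded below, with the −∞ sentinel for a
zero original Brier.

## Synthetic data generators

The generators emulate the *shape and statistical structure* of three
kinds of small biomedical datasets, not any real dataset's values; an
optional download is deliberately not part of the package, and no test
depends on external data.

* **Inflammation-like** (default n = 120): temperature uniform on
  [35.5, 42.5) rounded to 0.1 °C, six Bernoulli(½) symptoms, and two
  binary diagnosis targets that are deterministic rules
  (urine pushing ∧ micturition pains; temperature ≥ 39 ∧ lumbar pain)
  with symmetric label-flip noise (default 0). The temperature hierarchy
  cuts at 35/37/39/41/43 °C, so one lattice level exactly preserves the
  39 °C rule boundary — by design the anonymizer *can* keep the signal
  while coarsening, and whether it does is what the tests measure.
* **Cytopathology-like** (default n = 699): nine ordinal 1–10 scores,
  binary malignancy from a logistic model dominated by the first score
  (weight 1.5 vs 0.05), optional missing-cell rate (cells become the
  `NA` category with its own hierarchy path). Score hierarchies merge
  ranges pairwise up to `*`.
* **Contraceptive-like** (default n = 1473): a 3-class target drawn from
  a configured mixture (defaults 0.43/0.35/0.22), with age, parity and
  education sampled conditionally on the class and several independent
  nuisance attributes; age uses a 5-year → wider-band interval
  hierarchy.
* **Worked-example fixture**: a fixed five-record table with a
  data-independent scheme that generalizes all quasi-identifiers into
  one class, a fixed Bernoulli(3/5) sampling draw keeping exactly three
  records (the sampling seed is part of the fixture definition), and
  k = 3 suppression — giving the recomputable guarantees max risk 1/3,
  ε ≈ 0.92, δ ≈ 0.22.

Label noise is a symmetric flip because its effect on attainable AUC is
predictable; the generators do not reproduce real data's correlated
missingness, measurement artefacts, or class-dependent feature noise.
Passing tests therefore demonstrate that the machinery preserves
*planted, rule-like* structure under anonymization — not that any
particular real dataset would retain a specific AUC.

## Numerical and design choices

* Suppression token `*` everywhere (matches the hierarchy root
  convention); text comparisons are exact, no case folding.
* Default suppression limit 1.0 (permissive); the limit interacts with
  feasibility and is part of the result metadata.
* delta-bound truncation tolerance 10⁻¹⁵ relative to the running
  maximum; k ceiling 10⁵; lattice ceiling 10⁶ nodes.
* The evaluation defaults to 10 folds; the bundled small-n examples and
  long-running property suites use 5 folds and 50-tree forests, which
  keeps per-fold class counts comfortable at n ≈ 120 and 20-seed
  replications cheap.
* Seeds: every stochastic step (sampling, exponential mechanism, fold
  shuffling, forest construction) takes an explicit seed recorded in the
  corresponding result object; there is no hidden global state.

## Limitations

* Generalization is global (full-domain) only; per-record (local)
  generalization is out of scope, as are l-diversity/t-closeness-style
  criteria, multi-release composition accounting, and regression or
  time-to-event targets.
* The exhaustive search favours auditability over speed: lattices beyond
  ~10⁵ nodes become slow, and the 10⁶-node refusal is deliberate.
* The DP score's sensitivity constant is verified empirically on
  neighboring-dataset sweeps, not proven here.
* Character-level masking is representable as an ordinary hierarchy but
  has no dedicated builder.
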