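# Methods

`fctf` implements a food–components–target–function (FCTF) evaluation
chain for medicinal-food data: starting from a chemical component library,
a component→target prediction table and a target→disease catalog, it mines
association rules over *targets*, weights the rule measures objectively,
ranks the rules, and screens targets that carry evidence on both the
chemistry side and the disease side. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not show.

## Data model and screening rules

Inputs are plain CSV/TSV snapshots exported from public databases (the tool
performs no live retrieval). Normalisation is fixed: gene symbols are
upper-cased, component names lower-cased, disease names compared
case-insensitively after whitespace collapse. Every screening filter is a
**strict** inequality; values exactly at a threshold are excluded:

| filter | default | meaning |
| --- | --- | --- |
| component relative content | > 1 % | kept if it exceeds the cut under *any* detection method (max over methods; the per-method mean is reporting-only) |
| target prediction probability | > 0 | unitless score in [0, 1]; duplicate (component, target) rows keep the maximum |
| protein interaction combined score | > 0.9 | STRING-style; raw 0–1000 columns are auto-detected (any value > 1) and divided by 1000; a column mixing both scales is rejected rather than guessed |
| docking binding energy | < −5.0 kcal/mol | flags favourable binding; parsing/thresholding only, no docking is computed |
| enrichment terms | p < 0.01, top 20 per ontology | ties at equal p break by descending gene count then term id |

## Transactions and association rules

Each *index entity* — one component or one disease — contributes one
transaction: its set of associated target symbols. The default mode uses
both kinds together (`both`); components-only and functions-only modes
exist because the choice of transaction universe changes N and therefore
every support value. Diseases enter as deduplicated disease *names*, not
categories: a handful of categories would give too few transactions for
support fractions in a meaningful range.

Frequent target itemsets (default maximum size 2, matching the X→Y shape
of reported rule tables; configurable upward) are found by level-wise
Apriori with prefix-join candidate generation and downward-closure pruning.
For a frequent itemset, every ordered partition into disjoint non-empty
antecedent Tx and consequent Ty yields a rule scored from exact occurrence
counts:

- support = P(Tx ∪ Ty)/N
- confidence = P(Tx ∪ Ty)/P(Tx)
- lift = confidence / support(Ty)
- leverage = support − support(Tx)·support(Ty)
- conviction = (1 − support(Ty)) / (1 − confidence)

Conviction divides by zero at confidence = 1; it is reported as +inf,
serialised as the string `"inf"`, and passes any finite lower bound.
Default rule screen: support > 20 %, confidence > 35 %, lift > 1,
leverage > 0, conviction > 0 (all strict). Support/confidence thresholds
given as values > 1 are interpreted as percents. Output ordering is fully
deterministic (support desc, confidence desc, rule label).

The implementation is cross-checked in the test suite against an
exhaustive power-set enumerator that recounts occurrences directly from raw
transactions and shares no code with the Apriori path; agreement is exact
(float-for-float), not approximate.

## Entropy weights and TOPSIS

Filtered rules form a decision matrix over the five measures, all treated
as benefit criteria. The entropy weight method uses proportion
normalisation p_ij = x_ij/Σ_i x_ij and e_j = −(1/ln n) Σ_i p_ij ln p_ij
(0·ln 0 := 0), w_j = (1 − e_j)/Σ_k (1 − e_k); this is the canonical
formulation, stated here explicitly so results are auditable. Infinite
conviction entries are capped at the finite column maximum before analysis;
columns containing negatives are min-shifted to be non-negative for the
entropy step. A constant column gets entropy 1 and weight 0. If *every*
column is constant the weights are undefined; `entropy_weights` raises, and
the composed `rank_rules` falls back to documented equal weights (this
occurs legitimately when only a symmetric pair of rules survives
filtering).

TOPSIS uses vector (Euclidean) normalisation — the canonical choice, which
makes scores invariant to positive rescaling of any single column — then
weights columns, takes per-column max/min as positive/negative ideals, and
scores C = d⁻/(d⁺ + d⁻) ∈ [0, 1]. An alternative coinciding with the
positive ideal scores exactly 1; ties in the ranking break
lexicographically on the rule label so output is deterministic.

## Bidirectional targets and classifier evaluation

A target is *bidirectional* when it is associated with more than two
distinct components **and** more than two distinct diseases (strict, i.e.
≥ 3 of each; both cuts configurable). Separability of that class is probed
with two standard classifiers — a 200-tree random forest with Gini
importances and an RBF support-vector machine on standardised features —
using stratified K-fold cross-validation (default 5 folds, reduced with a
warning when a class is smaller) with out-of-fold scores pooled into a
single ROC per model. Pooling was chosen over per-fold averaging to give
one curve with every sample scored exactly once. The forest is scored by
its class-1 probability and the SVM by its signed margin distance — ROC
and AUC depend only on score ordering, so margins serve without the extra
internal calibration a probability estimate would require. The features are
per-target: the two degrees, antecedent/consequent rule counts, and the
strongest support and confidence of any rule mentioning the target.

Because the degree features *encode the screening rule*, near-perfect AUC
on this task demonstrates self-consistency, not biological signal; the
`drop_degree_features` flag removes them as a leakage check. The feature
schema is this package's own reconstruction of an under-specified
evaluation design, and no claim is made that its AUC values transfer to any
particular published experiment.

## Synthetic data

The generator emulates the *shape* of a real snapshot: log-normal relative
contents (mu = 0, sigma = 1.5 → a few dominant components, many trace
ones) under two detection methods, so the max-over-methods screen is
exercised; Bernoulli component→target and target→disease edges; uniform
(0, 1] prediction probabilities; round-robin disease categories so every
category is populated for overlap tests. Defaults: 30 components,
15 targets, 20 diseases (50 index entities), 5 categories, edge densities
0.25 — small enough that the whole pipeline runs in well under a second
per seed while random pairs rarely pass the default rule screen.

Planted pairs inject signal: any index entity containing *either* member of
a planted pair gains the other member with the boost probability. The
symmetric form is used because it is what "high co-occurrence" means
operationally: with boost b the pair's joint support approaches
P(either member drawn), comfortably above the 20 % support cut at the
default densities, whereas boosting only one direction leaves the joint
support hovering at the threshold and recovery becomes a coin flip on the
binomial sampling noise. With boost 0.95 the full mine → filter → rank
chain places the planted pair at rank 1 in essentially every seed; with no
planted pairs, emitted rules have leverage centred near zero and the
fraction of pairs passing all five thresholds is far below the planted
case.

What the synthetic data deliberately do **not** model: realistic chemistry
or content correlations between methods, disease ontology structure,
correlated target modules (edges are independent Bernoulli draws apart
from planted pairs), and database-specific artefacts such as redundant
symbols. Passing tests therefore certify the algorithms and their
contracts, not the biology of any particular food.

## Numerical and design choices

- Counts are exact integers; supports are integer ratios evaluated in
  floating point. The worked-example reference table stores each value as
  the literal arithmetic of its defining formula so comparisons are exact.
- "More than two" in bidirectional screening is implemented strictly
  (> 2), consistent with reported degree examples of 3 and 4.
- Degree tables and Venn regions sort deterministically (degree desc, then
  lexicographic; region keys sorted).
- The full pipeline restricts predictions to screened components before
  mining, mirroring the workflow in which targets are predicted only for
  abundant components.
- Optional pipeline stages (classifiers, gene-set intersection, docking /
  enrichment / interaction reporting) record a failure in the run report
  without aborting; mandatory stages abort with a partial manifest and a
  non-zero exit status.
- Problem sizes in tests and the acceptance script (100 random databases
  of ≤ 12 items × ≤ 30 transactions for oracle equivalence; 20-seed
  sweeps for recovery and null calibration; n = 200 for classifier
  sanity) were chosen as the smallest scales at which each property is
  statistically meaningful.

## Known limitations

- The transaction universe of a published analysis (components + diseases,
  components only, deduplicated or not) is rarely stated; results depend
  on it through N. The `mode` switch makes the choice explicit rather than
  silently fixing it.
- Reproducing any specific published rule table requires that study's
  exported snapshots; this package ships none and treats such tables as
  ordinary inputs through the column-mapping dialect.
- Apriori is the only mining algorithm (no FP-Growth), degree the only
  centrality, and no redundancy pruning is applied beyond the five
  thresholds.
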