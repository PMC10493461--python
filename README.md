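# fctf

Association-rule mining for food efficacy research: from a chemical
component library and component→target / target→disease association
tables, `fctf` mines Apriori rules over **targets**, scores each rule
Tx → Ty with five measures, weights the measures objectively by the
entropy-weight method (EWM), ranks rules by TOPSIS, screens *bidirectional*
targets (supported by both chemistry and disease evidence) and back-maps
key targets to their active components.

It is aimed at network-pharmacology-style studies of complex foods and
herbal preparations, where each component is an index entity carrying a
set of predicted protein targets and each disease carries a set of
associated targets, and the question is which target co-occurrence
patterns are strong, reliable and worth validating.

## The model

Each component and each disease contributes one transaction: its target
set. Over N transactions, with P(S) the number of transactions containing
the target set S:

```
support(Tx→Ty)    = P(Tx ∪ Ty) / N
confidence(Tx→Ty) = P(Tx ∪ Ty) / P(Tx)
lift(Tx→Ty)       = confidence(Tx→Ty) / support(Ty)
leverage(Tx→Ty)   = support(Tx→Ty) − support(Tx)·support(Ty)
conviction(Tx→Ty) = (1 − support(Ty)) / (1 − confidence(Tx→Ty))
```

Rules are screened by strict thresholds (defaults: support > 20 %,
confidence > 35 %, lift > 1, leverage > 0, conviction > 0), the surviving
rules form a decision matrix, EWM assigns each measure a weight from its
information entropy, and TOPSIS scores each rule by closeness to the ideal
C = d⁻/(d⁺ + d⁻). See `docs/methods.md` for formulas, edge cases and
design choices.

## Worked example

The bundled micro fixture has three components and one disease over
targets A, B, C — four transactions `{A,B}, {A,B,C}, {A}, {B,C}`:

```python
>>> from fctf import worked_example, build_transactions, \
...     mine_frequent_itemsets, derive_rules, filter_rules, rank_rules
>>> ex = worked_example()
>>> tx = build_transactions(ex.predictions, ex.functions)
>>> tx.N
4
>>> rules = derive_rules(mine_frequent_itemsets(tx, 0.2, 2), tx)
>>> for r in sorted(rules, key=lambda r: r.label)[:2]:
...     print(r.label, round(r.support, 4), round(r.confidence, 4),
...           round(r.lift, 4), round(r.leverage, 4), round(r.conviction, 4))
A -> B 0.5 0.6667 0.8889 -0.0625 0.75
A -> C 0.25 0.3333 0.6667 -0.125 0.75
>>> [r.label for r in filter_rules(rules)]
['C -> B', 'B -> C']
>>> rank_rules(filter_rules(rules)).table[["rank", "antecedent", "consequent", "score"]]
   rank antecedent consequent  score
0     1          C          B    1.0
1     2          B          C    0.0
```

A → B has lift 8/9 < 1 (A and B co-occur *less* than independence
predicts) and is dropped by the screen; C → B holds with confidence 1, so
its conviction is the +inf sentinel, and it dominates the ranking. The
same numbers are hand-derivable from the four transactions, and the test
suite checks them float-for-float against an exhaustive power-set oracle.

At realistic scale, `fctf simulate` generates a synthetic snapshot (30
components, 15 targets, 20 diseases by default, optionally with planted
high-co-occurrence target pairs) and the pipeline runs end to end from a
YAML config:

```
fctf simulate --seed 3 --planted T001 T002 0.95 --out sim
fctf run --config fctf.yaml      # ingest → screen → network → mine → rank → screen-targets
```

producing `rules.tsv`, `ranked_rules.tsv`, `weights.json`, degree tables,
`bidirectional_targets.tsv` and a `run_report.json` with per-stage counts
and output checksums. With the planted pair above, the top-ranked rule is
`T002 -> T001` (support 0.47, confidence 1.0, lift 2.04, conviction inf).

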