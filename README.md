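# catform

**XML-defined psychometric instruments with IRT scoring, exhaustive lookup
tables, pre-computed adaptive testing, and a policy-enforcing session engine.**

## The problem

Patient-reported outcome instruments — think of a video-animated mobility
questionnaire administered to older adults on a touchscreen — are usually
hard-coded into the software that presents them. Every variation of the item
set then means editing forms, processing scripts and database schemas by
hand. `catform` separates the *instrument* from the *engine*: a complete
questionnaire (presentation policies, localized instructions and practice
items, ordered items with media keys, shared response categories, and the
scoring mechanism) lives in one XML document, and a generic engine
administers it, enforces its policies, records sessions, computes scores and
exports a single analysis table. Creating a variant of a study instrument
means editing one XML file.

The package is for psychometricians and study engineers who need to define,
validate and administer such instruments, and to pre-compute their scoring
artifacts.

## The model

Scoring rests on item response theory. For a dichotomous item with
discrimination *a* and difficulty *b*, the probability of an affirmative
response at latent trait θ follows the two-parameter logistic model

P(X=1 | θ) = 1 / (1 + exp(−a(θ − b))),

and K-category ordered items follow Samejima's graded response model.
Trait scores are expected a posteriori (EAP): the posterior mean of θ under a
standard-normal prior on a fixed quadrature grid, with the posterior SD as
the standard error. Because EAP is deterministic and cheap, it can be cached
exhaustively:

- **Lookup tables** — the scores of *all* Π<sub>i</sub> r<sub>i</sub>
  possible response patterns, written to a two-column file; runtime scoring
  is one exact-match retrieval.
- **CAT trees** — every fixed-length adaptive administration of *n* items
  from an *m*-item bank, pre-computed as a complete binary tree with
  2<sup>n+1</sup>−1 nodes. The root presents the maximum-Fisher-information
  item at the prior mean; "no" descends left, "yes" right; each non-root node
  stores the EAP score and SE of its path, and leaves hold final scores.
  Administration is pointer-chasing (O(1) per item), so adaptive testing runs
  on the weakest hardware. Pre-computation grows as O(2<sup>n</sup>) and is
  capped at n = 20; in practice precision plateaus around 10–12 items.

## Worked example

```python
from catform import (FixtureConfig, ResponsePattern, build_instrument,
                     build_lookup_table, generate_item_bank, score_lookup)

config = FixtureConfig(seed=3, items=3, responses=2, with_instructions=False)
instrument = build_instrument(config)
bank = generate_item_bank(config)          # a ~ U[1,2], b spread over [-2,2]
table = build_lookup_table(instrument, bank)
print(len(table))                          # 8  (= 2^3 patterns)
print(score_lookup(table, ResponsePattern(values=(1.0, 0.0, 1.0))))
```

prints `8` and `0.0312`: the yes–no–yes pattern maps to an EAP trait
estimate of +0.03 — slightly above the population mean, because two of the
three answers were affirmative and the affirmed items were the easier ones.
The full table for this instrument runs from −1.09 (all no) to +0.94
(all yes), and every entry equals the directly computed EAP for its pattern.

The `examples/` directory has one runnable script per capability: defining
and validating instruments, lookup-table scoring, adaptive trees, session
administration with policies/export/submission, and cohort simulation.

A command line binds the same operations:

```sh
catform validate instrument.xml
catform build-table --instrument instrument.xml --bank bank.tsv --out scores.tsv
catform build-cat --bank bank.tsv --length 12 --out tree.tsv
catform simulate --seed 7 --items 12 --cohort 100 --out-dir run/
catform administer instrument.xml --respondent-id p01
```

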