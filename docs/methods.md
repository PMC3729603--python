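# Methods

This note documents the models, conventions and numerical choices behind
`catform`, what the synthetic fixtures do and do not emulate, and the design
decisions taken where more than one reasonable reading existed.

## Instrument dialect

An instrument document has `instrument` as the root with four children:
`instrumentPolicies`, `instructions`, `items` and `scoring`. Items are
required; instructions and the score computation are optional, so the engine
never depends on them. The dialect of record is the XSD shipped at
`catform/data/instrument.xsd`; it describes the canonical serialization
order. The parser itself is strict about structure (required attributes,
localization rules, reference integrity) but deliberately order-lenient
within a parent, while the serializer emits one fixed canonical order —
equal objects serialize to identical bytes, so instrument variants diff
cleanly under version control.

Conventions fixed here because the dialect leaves them open:

- Policies are `<policy key="…" value="…"/>` entries. Boolean policies accept
  only `true`/`false` (case-insensitive); anything else is a validation
  error, so configurations are bit-exact. Unknown keys are rejected in
  strict mode and ignored otherwise.
- Category identifiers are an `id` attribute, matching items and responses.
- Localized text repeats the element once per locale with a `lang` attribute
  (BCP-47); the lang-less element is the default, and more than one default
  is an error. Resolution is exact tag > progressively shorter tag prefix
  (`en-GB` → `en`) > default; prefix fallback goes beyond the bare
  default-fallback rule because deployments see regionalized locales.
- A response label may be an attribute (one label for all locales) or child
  `label` elements.
- Media is referenced by key, never filename; a tab-separated manifest maps
  (key, platform, locale) to paths with `*` as the wildcard, and the most
  specific entry wins. The engine stops at returning a path — no playback.

Validation is data-oriented: `validate()` returns one violation record per
defect with a stable machine-readable code (`DUPLICATE_ITEM_ID`,
`NONCONTIGUOUS_NUMBERS`, `DANGLING_CATEGORY`, …). The fixture module can
seed a document with exactly one defect per code, which is how validator
completeness is tested code by code.

## Expression language

Mapping and scoring functions are arithmetic expressions over one variable,
`value`: numeric literals, `+ − * /`, unary minus, parentheses, nothing
else. The closed grammar is a safety property — a document can never smuggle
executable code. The parser is a small recursive-descent implementation with
positional errors; evaluation is pure and raises only on division by zero.

Two conventions the dialect needs but does not pin down:

- The **base numeric value** of a response is its 0-based ordinal within its
  category's response list; `mappingFunction` transforms that ordinal. The
  ordinal convention is deterministic and independent of response-id format.
- `scoringFunction` binds `value` to the **sum of mapped values** across the
  pattern — the classical sum-score convention for multi-item instruments —
  and the expression rescales or recenters it.

## IRT core

Dichotomous items use the 2PL model; polytomous items use Samejima's graded
response model (GRM), which reduces exactly to the 2PL at K = 2. These are
the standard choices for PROMIS-style self-report items, and the dichotomous
case is what a binary adaptive tree requires. Item parameter *calibration*
is out of scope: parameters arrive as inputs (tab-separated
`item_id  a  b_1 [b_2 …]`, thresholds strictly increasing), the way
calibration software would emit them.

Trait estimation is EAP — posterior mean and SD under a standard-normal
prior on a fixed grid. EAP was chosen over ML/MAP because it is
deterministic, well-defined for all-extreme patterns, costs one vector pass,
and is exactly what table and tree pre-computation cache. Fisher information
is `a²P(1−P)` for the 2PL and the category-information sum for the GRM.

Quadrature grids:

- **Interactive default: 61 equispaced points on [−4, 4]** with normalized
  N(0,1) weights. For short instruments this agrees with dense (10,001-point,
  [−6, 6]) trapezoidal integration to ≤ ~5×10⁻⁴ in θ̂.
- **Offline table building: 101 points on [−5, 5].** For longer instruments
  the posterior of all-extreme patterns leans into the tail, and truncation
  at ±4 alone contributes errors above 10⁻³ (measured ~1.7×10⁻³ for an
  8-item table). The error is truncation, not spacing, so the offline grid
  widens the bounds; since tables and trees are built once offline, the
  extra cost is irrelevant. `build_lookup_table` defaults to the offline
  grid; both builders accept any grid explicitly.

## Lookup tables

`enumerate_patterns` walks the full Π r_i pattern space (item-number-major,
response-ordinal order) under a cap of 2²⁰ entries by default — exceeding it
raises an explicit intractability error rather than grinding. Pattern keys
are the mapped values rendered as shortest exact decimals, comma-joined;
integral values render without a decimal point. The table file is
two-column, tab-separated, key-sorted, scores at six decimals — building the
same table twice is byte-identical. A mapping function that collapses two
patterns onto one key is rejected at build time, since an exhaustive table
needs injective keys.

## Adaptive trees

`build_tree` pre-computes the complete depth-n tree for a dichotomous bank:
the root presents the maximum-information item at the prior mean; each child
node presents the maximum-information *unused* item at the EAP θ̂ given the
path's responses (ties broken by lexicographic item id); every non-root node
stores that path's score and SE; depth-n leaves hold final scores. Depth is
hard-capped at 20 (the tree is O(2ⁿ)); the natural operating range is 10–12
items, where precision gains flatten out — measured on a seeded 20-item
bank, the mean-SE drop from 12 to 20 adaptive items is under 10% of the drop
from 1 to 12.

The tree file is level-order (node *i*'s children at 2i+1, 2i+2),
tab-separated with a `#depth=…  bank_ref=…` header; leaf records carry `*`
in the item column and the root's score fields are empty. Deserialization
checks the record count against the declared depth and rejects non-finite
scores; `validate_tree` re-checks structure (node count, per-path
distinctness, bank membership, positive SEs, score-less root) for
hand-edited files.

Two properties worth stating precisely:

- The tree is an *exact cache*: traversal reproduces an online adaptive run
  (fresh EAP, fresh max-information selection per step, same grid) item for
  item and digit for digit. The tests verify this against an independent
  reimplementation of the online run, exhaustively at depth 8 and on seeded
  random paths at depth 12.
- Stored SE is *not* strictly non-increasing along every path: a response
  that contradicts the path so far can widen the EAP posterior slightly
  (observed +0.009 at worst on a depth-6 fixture tree). What holds, and what
  the tests assert, is that mean SE per depth strictly decreases —
  information accumulates on average.

## Session engine

The engine is presentation-agnostic: it drives any adapter implementing
`show_instructions` / `ask` / `show_score` (a terminal adapter and a
scripted replay adapter ship with the package). Sessions walk items strictly
in number order — or down the adaptive tree for tree-scored instruments,
where the administered length is the tree depth, not the bank size. Practice
items are presented but never recorded. All timestamps come from an
injectable clock, so durations are exactly testable; they serialize as
ISO 8601 with timezone, durations as integer seconds.

Policy semantics, enforced at the documented point and nowhere else:

| policy | enforcement |
| --- | --- |
| `requireRespondentId` / `requireVisitCode` | session cannot start without the identifier |
| `requireVideoViewing` | a response is rejected unless a `media_completed` event for that item preceded it |
| `startVideoAutomatically` | presentation hint only; no engine-side gate (it has no observable engine semantics) |
| `showComputedScore` | gates score *visibility* to the adapter, never score computation |
| `serverSubmissionURL` | enables the submission queue; absent ⇒ enqueue is a no-op |

Discarded sessions are retained and flagged rather than deleted — safer than
deletion and equivalent for export, which emits exactly one CSV row per
*completed* session (identifiers, ISO start, duration, one column per item
id in number order, score). The store is a single JSON document; every save
first writes a timestamped backup of the previous state, and a corrupt store
raises an error naming the newest backup.

### Submission payload

Delivery is at-least-once: a session leaves the queue only on acknowledged
transport success; failures stay queued with the attempt logged. The wire
format is one self-contained JSON document:

```json
{"format": "catform-session", "version": 1,
 "session": {"session_id": "...", "respondent_id": "...", "visit_code": "...",
             "locale": "...", "start": "...", "end": "...", "score": 0.0,
             "status": "completed", "submitted": false,
             "responses": [{"item_id": "...", "response_id": "...",
                            "value": 0.0, "timestamp": "..."}]}}
```

The transport is a pluggable callable `(url, payload) -> bool`; the server
side is out of scope.

## Synthetic fixtures and what they show

The generators emulate the *shape* of a video-animated mobility instrument:
m items sharing one response category (default m = 12, K = 2 or 5; the
full-length shape is 81 items × 5 responses), optional instructions with a
practice item, per-locale label variants, and media keys with a manifest.
Item banks emulate calibration output: a ~ U[1, 2], thresholds spread over
[−2, 2] (strictly increasing, minimum gap 0.05). Cohorts draw
θ ~ N(0, 1) (configurable) and answer through the response model, driving
the full engine lifecycle. Everything is deterministic under its seed.

What the fixtures do **not** emulate: real item wording and media, real
calibrated parameters (the published instrument's parameters are not
public), local dependence between items, response styles
(acquiescence, careless responding), missingness, or device/timing effects.
Passing tests therefore demonstrate that the machinery is correct under the
stated models — not that any particular real instrument is well-calibrated.

Problem sizes used by the test suite and the acceptance script — 150
generated instruments plus 52 seeded-defect documents for the round-trip
and validator checks; 3- and 8-item exhaustive tables; trees to depth 12;
cohorts of 500 respondents — were chosen so every property is exercised at
meaningful scale while the whole suite stays interactive-fast.

## Known limitations

- Adaptive trees require dichotomous items (the tree is binary by
  construction); polytomous instruments score by table or function.
- No variable-length stopping rules, content balancing or exposure control —
  the design is fixed-length by intent.
- The expression language is deliberately minimal; it cannot express
  flooring/binning beyond what arithmetic allows.
- Lookup scores are raw θ on the prior's scale; any reporting rescale
  (T-scores etc.) is left to the consumer.
- The XSD validates the canonical serialized form; order-shuffled documents
  should be checked through the parser, which accepts any child order.
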