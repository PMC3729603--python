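"""Response-pattern enumeration, lookup-table scoring, and runtime scoring.

An instrument that scores by lookup table ships a two-column file mapping
every possible response sequence to a pre-computed real-valued score; at
administration time scoring is a single exact-match retrieval.  Exhaustive
enumeration is only tractable while the pattern space Π_i r_i stays small, so
enumeration is guarded by a configurable cap (default 2^20 patterns).

The base numeric value of a response is its 0-based ordinal within its
category's response list, optionally passed through the category's
mappingFunction expression; a pattern key is the mapped values rendered as
shortest exact decimals, comma-joined in item-number order.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import (
    CatformError,
    IntractableError,
    TableFileError,
    UnscorablePatternError,
)
from .expressions import Expression, evaluate, parse_expression
from .irt import AbilityEstimate, ItemParameters, QuadratureGrid, eap_estimate
from .model import Instrument, ScoringCategory

DEFAULT_PATTERN_CAP = 2**20

def _table_grid() -> QuadratureGrid:
    """Default quadrature for pre-computed tables: 101 points on [-5, 5].

    Exhaustive tables are built offline once, so the wider, denser grid costs
    nothing at administration time; it keeps all-extreme patterns of longer
    instruments (whose posteriors lean into the tail beyond ±4) accurate to
    well under 1e-3 against dense-grid integration.
    """
    return QuadratureGrid.standard_normal(101, 5.0)


@dataclass(frozen=True)
class ResponsePattern:
    """Mapped numeric response values, one per item, in item-number order."""

    values: tuple[float, ...]

    def key(self) -> str:
        return pattern_key(self.values)


@dataclass
class LookupTable:
    """Exhaustive map from canonical pattern key to real-valued score."""

    entries: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def _render_value(value: float) -> str:
    """Shortest exact decimal: integers without a point, floats via repr."""
    if value == int(value):
        return str(int(value))
    return repr(float(value))


def pattern_key(values: Sequence[float]) -> str:
    return ",".join(_render_value(v) for v in values)


def map_response(category: ScoringCategory, response_id: str) -> float:
    """Mapped numeric value of a response: its ordinal through the category's
    mapping function (identity when the category has none)."""
    for ordinal, resp in enumerate(category.responses):
        if resp.id == response_id:
            if category.mapping_function is None:
                return float(ordinal)
            return evaluate(parse_expression(category.mapping_function), float(ordinal))
    raise CatformError(
        f"response id {response_id!r} not found in category {category.id!r}"
    )


def _item_categories(instrument: Instrument) -> list[ScoringCategory]:
    return [instrument.category(it.scoring_category) for it in instrument.items_in_order()]


def _check_cap(counts: Sequence[int], cap: int) -> None:
    total = 1
    for c in counts:
        total *= c
        if total > cap:
            raise IntractableError(
                f"pattern space {'×'.join(map(str, counts))} exceeds the cap of {cap} entries"
            )


def enumerate_patterns(
    instrument: Instrument, cap: int = DEFAULT_PATTERN_CAP
) -> list[ResponsePattern]:
    """All possible response patterns, lexicographic in item-number-major
    response-ordinal order; count is the product of per-item response counts."""
    categories = _item_categories(instrument)
    counts = [len(cat.responses) for cat in categories]
    _check_cap(counts, cap)
    mapped = [
        [map_response(cat, resp.id) for resp in cat.responses] for cat in categories
    ]
    return [
        ResponsePattern(values=combo) for combo in itertools.product(*mapped)
    ]


def score_lookup(table: LookupTable, pattern: ResponsePattern) -> float:
    key = pattern.key()
    try:
        return table.entries[key]
    except KeyError:
        raise UnscorablePatternError(
            f"pattern {key!r} has no entry in the lookup table"
        ) from None


def score_function(expr: Expression, pattern: ResponsePattern) -> float:
    """Runtime score: the expression with ``value`` bound to the pattern sum.

    Summing the mapped values is the classical sum-score convention for
    multi-item instruments; the expression then rescales or bins it.
    """
    return evaluate(expr, float(sum(pattern.values)))


def build_lookup_table(
    instrument: Instrument,
    bank: Sequence[ItemParameters],
    grid: QuadratureGrid | None = None,
    cap: int = DEFAULT_PATTERN_CAP,
) -> LookupTable:
    """Pre-compute an exhaustive table of EAP trait scores.

    One entry per possible response pattern; the stored score is the EAP θ̂
    for that pattern under *bank* (one :class:`ItemParameters` per item, in
    item-number order).  Deterministic given the grid; when *grid* is omitted
    the wider offline table grid (101 points on [-5, 5]) is used.
    """
    if grid is None:
        grid = _table_grid()
    items = instrument.items_in_order()
    if len(bank) != len(items):
        raise CatformError(f"bank has {len(bank)} items, instrument has {len(items)}")
    categories = _item_categories(instrument)
    counts = [len(cat.responses) for cat in categories]
    for cat, params in zip(categories, bank):
        if len(cat.responses) != params.n_categories:
            raise CatformError(
                f"category {cat.id!r} has {len(cat.responses)} responses but item "
                f"{params.item_id!r} has {params.n_categories} IRT categories"
            )
    _check_cap(counts, cap)
    mapped = [
        [map_response(cat, resp.id) for resp in cat.responses] for cat in categories
    ]
    table = LookupTable()
    for ordinals in itertools.product(*(range(c) for c in counts)):
        key = pattern_key([mapped[i][k] for i, k in enumerate(ordinals)])
        if key in table.entries:
            raise CatformError(
                f"mapping function collapses two patterns onto key {key!r}; "
                "an exhaustive lookup table requires an injective mapping"
            )
        estimate: AbilityEstimate = eap_estimate(ordinals, bank, grid)
        table.entries[key] = estimate.theta
    return table


def read_lookup_table(path: str | Path) -> LookupTable:
    """Read a two-column tab-separated pattern→score file."""
    table = LookupTable()
    with open(path, newline="", encoding="utf-8") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 2:
                raise TableFileError(
                    f"expected 2 columns, got {len(row)}", line=lineno
                )
            key, score_text = row
            if key in table.entries:
                raise TableFileError(f"duplicate pattern key {key!r}", line=lineno)
            try:
                table.entries[key] = float(score_text)
            except ValueError:
                raise TableFileError(
                    f"score {score_text!r} is not a number", line=lineno
                ) from None
    return table


def write_lookup_table(table: LookupTable, path: str | Path) -> None:
    """Write the table deterministically (key-sorted, scores to 6 decimals)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for key in sorted(table.entries):
            writer.writerow([key, f"{table.entries[key]:.6f}"])
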