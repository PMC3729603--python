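"""Instrument object model and structural validation.

An *instrument* is a complete psychometric questionnaire definition: a list of
presentation policies, optional instructions with practice items, the ordered
test items themselves, and a scoring section holding reusable response
categories plus an optional automatic score computation.

Validation is data-oriented: :func:`validate` returns a list of
:class:`~catform.errors.Violation` records, one per structural defect, each
with a stable machine-readable code.  Parsing (``catform.xmlio``) runs the
same checks and raises if any fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from urllib.parse import urlparse

from .errors import Violation
from .localization import LocalizedText

# Violation codes, kept in one place so tools can enumerate them.
MULTIPLE_DEFAULT_TEXT = "MULTIPLE_DEFAULT_TEXT"
DUPLICATE_LOCALE = "DUPLICATE_LOCALE"
UNKNOWN_POLICY = "UNKNOWN_POLICY"
BAD_POLICY_VALUE = "BAD_POLICY_VALUE"
BAD_SUBMISSION_URL = "BAD_SUBMISSION_URL"
DUPLICATE_ITEM_ID = "DUPLICATE_ITEM_ID"
DUPLICATE_ITEM_NUMBER = "DUPLICATE_ITEM_NUMBER"
NONCONTIGUOUS_NUMBERS = "NONCONTIGUOUS_NUMBERS"
DANGLING_CATEGORY = "DANGLING_CATEGORY"
DUPLICATE_CATEGORY_ID = "DUPLICATE_CATEGORY_ID"
DUPLICATE_RESPONSE_ID = "DUPLICATE_RESPONSE_ID"
EMPTY_CATEGORY = "EMPTY_CATEGORY"
NO_ITEMS = "NO_ITEMS"
PRACTICE_ID_COLLISION = "PRACTICE_ID_COLLISION"
AMBIGUOUS_SCORE_METHOD = "AMBIGUOUS_SCORE_METHOD"
BAD_EXPRESSION = "BAD_EXPRESSION"

BOOLEAN_POLICY_KEYS = (
    "requireRespondentId",
    "requireVisitCode",
    "requireVideoViewing",
    "startVideoAutomatically",
    "showComputedScore",
)
POLICY_KEYS = BOOLEAN_POLICY_KEYS + ("serverSubmissionURL",)


@dataclass
class InstrumentPolicies:
    """Presentation/collection policies (the instrumentPolicies key-value list)."""

    require_respondent_id: bool = False
    require_visit_code: bool = False
    require_video_viewing: bool = False
    start_video_automatically: bool = False
    show_computed_score: bool = False
    server_submission_url: str | None = None


@dataclass
class ResponseOption:
    """One legal participant response: an id plus a localized label."""

    id: str
    label: LocalizedText


@dataclass
class ScoringCategory:
    """A reusable set of legal responses shared by one or more items.

    ``mapping_function`` is an optional arithmetic expression over the variable
    ``value`` that bins the response's base numeric value (its 0-based ordinal
    within ``responses``) into the scored value.
    """

    id: str
    responses: list[ResponseOption]
    mapping_function: str | None = None


@dataclass
class Item:
    """One test item: an id, a 0-based order index, a localized description,
    a media key (not a filename), and a reference to its response category."""

    id: str
    number: int
    description: LocalizedText
    media: str | None
    scoring_category: str


@dataclass
class Instructions:
    """Pre-test instructions and unscored practice items."""

    instruction_text: LocalizedText
    practice_items: list[Item] = field(default_factory=list)


class ScoreMethod(str, Enum):
    LOOKUP_TABLE = "lookup_table"
    SCORING_FUNCTION = "scoring_function"
    CAT_TREE = "cat_tree"


@dataclass
class ScoreComputation:
    """How the engine computes an overall score.

    Exactly one payload is populated: the filename of an exhaustive lookup
    table, a runtime scoring expression, or the filename of a pre-computed
    adaptive-testing tree.
    """

    method: ScoreMethod
    lookup_table_file: str | None = None
    scoring_expression: str | None = None
    cat_tree_file: str | None = None


@dataclass
class Instrument:
    """A complete instrument definition."""

    policies: InstrumentPolicies = field(default_factory=InstrumentPolicies)
    instructions: Instructions | None = None
    items: list[Item] = field(default_factory=list)
    categories: list[ScoringCategory] = field(default_factory=list)
    score_computation: ScoreComputation | None = None

    def category(self, category_id: str) -> ScoringCategory:
        for cat in self.categories:
            if cat.id == category_id:
                return cat
        raise KeyError(category_id)

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def items_in_order(self) -> list[Item]:
        return sorted(self.items, key=lambda it: it.number)


def _is_absolute_url(url: str) -> bool:
    parsed = urlparse(url)
    return bool(parsed.scheme) and bool(parsed.netloc)


def validate(instrument: Instrument) -> list[Violation]:
    """Check every structural invariant; return one violation per defect.

    An empty list means the instrument is well-formed: item ids and numbers
    unique, numbers contiguous from 0, every category reference resolvable,
    category ids and response ids unique, categories non-empty, practice item
    ids disjoint from test item ids, at most one score-computation payload,
    submission URL absolute if present, and every mapping/scoring expression
    parseable.
    """
    from .expressions import parse_expression  # local import avoids a cycle
    from .errors import ExpressionError

    out: list[Violation] = []

    if not instrument.items:
        out.append(Violation(NO_ITEMS, "items", "an instrument requires at least one item"))

    seen_ids: set[str] = set()
    seen_numbers: set[int] = set()
    for it in instrument.items:
        path = f"items/item[@id={it.id!r}]"
        if it.id in seen_ids:
            out.append(Violation(DUPLICATE_ITEM_ID, path, f"item id {it.id!r} repeated"))
        seen_ids.add(it.id)
        if it.number in seen_numbers:
            out.append(
                Violation(DUPLICATE_ITEM_NUMBER, path, f"item number {it.number} repeated")
            )
        seen_numbers.add(it.number)

    if instrument.items and seen_numbers != set(range(len(seen_numbers))):
        out.append(
            Violation(
                NONCONTIGUOUS_NUMBERS,
                "items",
                f"item numbers {sorted(seen_numbers)} do not form 0..{len(seen_numbers) - 1}",
            )
        )

    cat_ids: set[str] = set()
    for cat in instrument.categories:
        path = f"scoring/categories/category[@id={cat.id!r}]"
        if cat.id in cat_ids:
            out.append(Violation(DUPLICATE_CATEGORY_ID, path, f"category id {cat.id!r} repeated"))
        cat_ids.add(cat.id)
        if not cat.responses:
            out.append(Violation(EMPTY_CATEGORY, path, "category has no responses"))
        resp_ids: set[str] = set()
        for resp in cat.responses:
            if resp.id in resp_ids:
                out.append(
                    Violation(
                        DUPLICATE_RESPONSE_ID,
                        f"{path}/responses/response[@id={resp.id!r}]",
                        f"response id {resp.id!r} repeated within category {cat.id!r}",
                    )
                )
            resp_ids.add(resp.id)
        if cat.mapping_function is not None:
            try:
                parse_expression(cat.mapping_function)
            except ExpressionError as exc:
                out.append(Violation(BAD_EXPRESSION, f"{path}/mappingFunction", str(exc)))

    practice = instrument.instructions.practice_items if instrument.instructions else []
    all_items = list(instrument.items) + list(practice)
    for it in all_items:
        if it.scoring_category not in cat_ids:
            out.append(
                Violation(
                    DANGLING_CATEGORY,
                    f"item[@id={it.id!r}]",
                    f"item {it.id!r} references undeclared category {it.scoring_category!r}",
                )
            )

    practice_ids = [it.id for it in practice]
    for pid in practice_ids:
        if pid in seen_ids:
            out.append(
                Violation(
                    PRACTICE_ID_COLLISION,
                    f"instructions/practiceItems/item[@id={pid!r}]",
                    f"practice item id {pid!r} collides with a test item id",
                )
            )

    comp = instrument.score_computation
    if comp is not None:
        payloads = [
            comp.lookup_table_file is not None,
            comp.scoring_expression is not None,
            comp.cat_tree_file is not None,
        ]
        if sum(payloads) != 1:
            out.append(
                Violation(
                    AMBIGUOUS_SCORE_METHOD,
                    "scoring/scoreComputation",
                    "exactly one of lookupTable, scoringFunction, catTree must be given",
                )
            )
        if comp.scoring_expression is not None:
            try:
                parse_expression(comp.scoring_expression)
            except ExpressionError as exc:
                out.append(
                    Violation(BAD_EXPRESSION, "scoring/scoreComputation/scoringFunction", str(exc))
                )

    url = instrument.policies.server_submission_url
    if url is not None and not _is_absolute_url(url):
        out.append(
            Violation(
                BAD_SUBMISSION_URL,
                "instrumentPolicies/serverSubmissionURL",
                f"{url!r} is not an absolute URL",
            )
        )

    return out
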