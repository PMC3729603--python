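"""Synthetic instruments, item banks, defect fixtures, and simulated cohorts.

Real instrument content (item wording, animations, calibrated parameters) is
proprietary to each study, so everything here is generated: instruments shaped
like a video-animated mobility questionnaire (many items sharing one response
category, policies, instructions with practice items, optional multi-locale
labels), item banks shaped like typical calibration output (discriminations
uniform on [1, 2], difficulties/thresholds spread over [-2, 2]), and cohorts
of simulated respondents with normally distributed latent traits.  Every
generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lxml import etree

from .errors import CatformError
from .irt import ItemParameters, simulate_response
from .localization import LocalizedText, MediaManifest
from . import model
from .model import (
    Instructions,
    Instrument,
    InstrumentPolicies,
    Item,
    ResponseOption,
    ScoreComputation,
    ScoreMethod,
    ScoringCategory,
)
from .xmlio import serialize_instrument

_WORDS = (
    "walk", "climb", "carry", "reach", "stand", "kneel", "lift", "bend",
    "step", "turn", "push", "pull", "balance", "stretch", "sit", "rise",
)
_LOCALE_PREFIX = {"es": "es:", "fr": "fr:", "de": "de:", "pt-BR": "pt:"}


@dataclass(frozen=True)
class FixtureConfig:
    """Geometry and conditions for generated fixtures.

    ``items`` (m) and ``responses`` (K) set the instrument shape; ``length``
    (n ≤ m) the adaptive test length; ``cohort`` (N) the number of simulated
    respondents with trait θ ~ Normal(theta_mean, theta_sd).  A seed is
    mandatory: every stochastic output is reproducible.
    """

    seed: int
    items: int = 12
    responses: int = 2
    locales: tuple[str, ...] = ()
    length: int | None = None  # defaults to min(12, items)
    cohort: int = 100
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    policies: InstrumentPolicies = field(default_factory=InstrumentPolicies)
    with_instructions: bool = True
    score_method: ScoreMethod | None = None
    score_payload: str | None = None

    def __post_init__(self) -> None:
        if self.items < 1:
            raise CatformError("an instrument needs at least one item")
        if self.responses < 2:
            raise CatformError("a category needs at least two responses")
        if self.length is None:
            object.__setattr__(self, "length", min(12, self.items))
        if not 1 <= self.length <= self.items:
            raise CatformError("test length must satisfy 1 <= n <= items")


def _localized(rng: np.random.Generator, base: str, locales: Sequence[str]) -> LocalizedText:
    variants = {
        loc: f"{_LOCALE_PREFIX.get(loc, loc + ':')}{base}" for loc in locales
    }
    return LocalizedText(default_text=base, variants=variants)


def build_instrument(config: FixtureConfig) -> Instrument:
    """A valid in-memory instrument with the configured geometry."""
    rng = np.random.default_rng(config.seed)
    words = [str(_WORDS[int(rng.integers(len(_WORDS)))]) for _ in range(config.items)]

    if config.responses == 2:
        response_ids = ["no", "yes"]
    else:
        response_ids = [f"r{k}" for k in range(config.responses)]
    responses = [
        ResponseOption(id=rid, label=_localized(rng, rid.capitalize(), config.locales))
        for rid in response_ids
    ]
    category = ScoringCategory(id="c-main", responses=responses)

    items = [
        Item(
            id=f"i{index:03d}",
            number=index,
            description=_localized(rng, f"Can you {words[index]}?", config.locales),
            media=f"m{index:03d}",
            scoring_category=category.id,
        )
        for index in range(config.items)
    ]

    instructions = None
    if config.with_instructions:
        practice = [
            Item(
                id="p000",
                number=0,
                description=_localized(rng, "Practice: can you wave?", config.locales),
                media="p000",
                scoring_category=category.id,
            )
        ]
        instructions = Instructions(
            instruction_text=_localized(
                rng, "Watch each animation, then choose the answer that fits best.",
                config.locales,
            ),
            practice_items=practice,
        )

    computation = None
    if config.score_method is not None:
        computation = ScoreComputation(method=config.score_method)
        payload = config.score_payload or ""
        if config.score_method is ScoreMethod.LOOKUP_TABLE:
            computation.lookup_table_file = payload
        elif config.score_method is ScoreMethod.SCORING_FUNCTION:
            computation.scoring_expression = payload or "value"
        else:
            computation.cat_tree_file = payload

    return Instrument(
        policies=config.policies,
        instructions=instructions,
        items=items,
        categories=[category],
        score_computation=computation,
    )


def generate_instrument(config: FixtureConfig) -> tuple[str, MediaManifest]:
    """Serialized instrument XML plus a matching media manifest.

    The manifest carries one default entry per media key and, for each
    requested locale, a locale-specific entry — enough to exercise the full
    media-resolution specificity order.
    """
    instrument = build_instrument(config)
    manifest = MediaManifest()
    all_items = list(instrument.items)
    if instrument.instructions:
        all_items += instrument.instructions.practice_items
    for item in all_items:
        if item.media is None:
            continue
        manifest.add(item.media, "*", "*", f"media/{item.media}.ogv")
        for locale in config.locales:
            manifest.add(item.media, "terminal", locale, f"media/{locale}/{item.media}.ogv")
    return serialize_instrument(instrument), manifest


def generate_item_bank(config: FixtureConfig) -> list[ItemParameters]:
    """Synthetic calibration output: a ~ U[1,2], thresholds spread on [-2,2]."""
    rng = np.random.default_rng(config.seed)
    bank: list[ItemParameters] = []
    n_thresholds = config.responses - 1
    for index in range(config.items):
        a = float(rng.uniform(1.0, 2.0))
        if n_thresholds == 1:
            thresholds = (float(rng.uniform(-2.0, 2.0)),)
        else:
            cuts = np.sort(rng.uniform(-2.0, 2.0, size=n_thresholds))
            # enforce strict increase with a minimal gap
            for j in range(1, n_thresholds):
                if cuts[j] <= cuts[j - 1]:
                    cuts[j] = cuts[j - 1] + 0.05
            thresholds = tuple(float(c) for c in cuts)
        bank.append(ItemParameters(f"i{index:03d}", a, thresholds))
    return bank


# ---------------------------------------------------------------------------
# Seeded-defect documents (one structural defect each, by violation code)
# ---------------------------------------------------------------------------


def _mutate(xml_text: str, mutator) -> str:
    root = etree.fromstring(xml_text.encode("utf-8"))
    mutator(root)
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode(
        "utf-8"
    )


def _defect_duplicate_item_id(root) -> None:
    items = root.findall("items/item")
    items[1].set("id", items[0].get("id"))


def _defect_duplicate_item_number(root) -> None:
    items = root.findall("items/item")
    items[-1].set("number", items[-2].get("number"))


def _defect_noncontiguous(root) -> None:
    items = root.findall("items/item")
    items[-1].set("number", str(len(items) + 5))


def _defect_dangling_category(root) -> None:
    el = root.find("items/item/scoringCategory")
    el.text = "no-such-category"


def _defect_duplicate_response_id(root) -> None:
    responses = root.findall("scoring/categories/category/responses/response")
    responses[1].set("id", responses[0].get("id"))


def _defect_empty_category(root) -> None:
    categories = root.find("scoring/categories")
    extra = etree.SubElement(categories, "category")
    extra.set("id", "c-empty")
    etree.SubElement(extra, "responses")


def _defect_duplicate_category_id(root) -> None:
    categories = root.find("scoring/categories")
    first = categories.find("category")
    extra = etree.SubElement(categories, "category")
    extra.set("id", first.get("id"))
    responses = etree.SubElement(extra, "responses")
    resp = etree.SubElement(responses, "response")
    resp.set("id", "only")
    resp.set("label", "Only")


def _defect_practice_collision(root) -> None:
    practice = root.find("instructions/practiceItems/item")
    test_item = root.find("items/item")
    practice.set("id", test_item.get("id"))


def _defect_multiple_default_text(root) -> None:
    item = root.find("items/item")
    extra = etree.Element("description")
    extra.text = "A second lang-less description"
    item.insert(1, extra)


def _defect_bad_policy_value(root) -> None:
    policies = root.find("instrumentPolicies")
    policy = etree.SubElement(policies, "policy")
    policy.set("key", "requireRespondentId")
    policy.set("value", "maybe")


def _defect_unknown_policy(root) -> None:
    policies = root.find("instrumentPolicies")
    policy = etree.SubElement(policies, "policy")
    policy.set("key", "frobnicate")
    policy.set("value", "true")


def _defect_bad_submission_url(root) -> None:
    policies = root.find("instrumentPolicies")
    policy = etree.SubElement(policies, "policy")
    policy.set("key", "serverSubmissionURL")
    policy.set("value", "not an absolute url")


def _defect_bad_expression(root) -> None:
    category = root.find("scoring/categories/category")
    etree.SubElement(category, "mappingFunction").text = "exp(value)"


DEFECTS: dict[str, object] = {
    model.DUPLICATE_ITEM_ID: _defect_duplicate_item_id,
    model.DUPLICATE_ITEM_NUMBER: _defect_duplicate_item_number,
    model.NONCONTIGUOUS_NUMBERS: _defect_noncontiguous,
    model.DANGLING_CATEGORY: _defect_dangling_category,
    model.DUPLICATE_RESPONSE_ID: _defect_duplicate_response_id,
    model.EMPTY_CATEGORY: _defect_empty_category,
    model.DUPLICATE_CATEGORY_ID: _defect_duplicate_category_id,
    model.PRACTICE_ID_COLLISION: _defect_practice_collision,
    model.MULTIPLE_DEFAULT_TEXT: _defect_multiple_default_text,
    model.BAD_POLICY_VALUE: _defect_bad_policy_value,
    model.UNKNOWN_POLICY: _defect_unknown_policy,
    model.BAD_SUBMISSION_URL: _defect_bad_submission_url,
    model.BAD_EXPRESSION: _defect_bad_expression,
}


def generate_defective_document(code: str, seed: int) -> str:
    """A document seeded with exactly one defect of the given violation code.

    Lenient re-parsing of the result yields that code (and only that code),
    which pins the validator's completeness code by code.
    """
    try:
        mutator = DEFECTS[code]
    except KeyError:
        raise CatformError(f"no defect generator for code {code!r}") from None
    config = FixtureConfig(seed=seed, items=4, responses=3, with_instructions=True)
    xml_text, _ = generate_instrument(config)
    return _mutate(xml_text, mutator)


# ---------------------------------------------------------------------------
# Simulated cohorts
# ---------------------------------------------------------------------------


class _ThetaAdapter:
    """Answers each presented item by sampling from the response model at a
    fixed latent trait — works for linear and adaptive administrations."""

    def __init__(self, theta: float, bank_by_item: dict[str, ItemParameters], rng):
        self.theta = theta
        self.bank = bank_by_item
        self.rng = rng

    def show_instructions(self, text: str) -> None:
        pass

    def ask(self, item, labels, practice: bool) -> str:
        if practice:
            return labels[0][0]
        params = self.bank[item.id]
        category = simulate_response(self.theta, params, self.rng)
        return labels[category][0]

    def show_score(self, score: float) -> None:
        pass


def simulate_cohort(
    instrument: Instrument,
    bank: Sequence[ItemParameters],
    config: FixtureConfig,
    *,
    table=None,
    tree=None,
    clock=None,
):
    """Drive N full sessions through the engine with simulated respondents.

    Returns ``(sessions, thetas)``.  Each respondent's trait is drawn from
    Normal(theta_mean, theta_sd); item responses come from the IRT response
    model, so recovered scores can be compared against the generating traits.
    """
    from .adapters import administer
    from .session import system_clock

    by_item = {p.item_id: p for p in bank}
    missing = [it.id for it in instrument.items if it.id not in by_item]
    if missing:
        raise CatformError(f"bank lacks parameters for items: {missing}")
    rng = np.random.default_rng(config.seed)
    thetas = rng.normal(config.theta_mean, config.theta_sd, size=config.cohort)
    sessions = []
    for index, theta in enumerate(thetas):
        adapter = _ThetaAdapter(float(theta), by_item, rng)
        session = administer(
            instrument,
            adapter,
            session_id=f"sim-{config.seed}-{index:04d}",
            clock=clock or system_clock,
            respondent_id=f"resp-{index:04d}",
            table=table,
            tree=tree,
        )
        sessions.append(session)
    return sessions, thetas
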