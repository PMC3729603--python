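"""Reading and writing instrument definition documents.

The dialect has ``instrument`` as the root with four children —
``instrumentPolicies``, ``instructions``, ``items`` and ``scoring``.  Parsing
is strict about structure (required attributes and children, localization
rules, reference integrity) but lenient about the order of elements within a
parent.  Serialization emits one fixed canonical order so that re-serializing
the same object is byte-identical and instrument variants diff cleanly under
version control.

A machine-readable XSD for the canonical form ships with the package
(``catform/data/instrument.xsd``); :func:`xsd_validate` checks a document
against it via lxml.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

from lxml import etree

from .errors import SchemaError, Violation
from .localization import LocalizedText
from .model import (
    BAD_POLICY_VALUE,
    BOOLEAN_POLICY_KEYS,
    DUPLICATE_LOCALE,
    MULTIPLE_DEFAULT_TEXT,
    POLICY_KEYS,
    UNKNOWN_POLICY,
    Instructions,
    Instrument,
    InstrumentPolicies,
    Item,
    ResponseOption,
    ScoreComputation,
    ScoreMethod,
    ScoringCategory,
    validate,
)

XML_SYNTAX = "XML_SYNTAX"
WRONG_ROOT = "WRONG_ROOT"
MISSING_CHILD = "MISSING_CHILD"
MISSING_ATTRIBUTE = "MISSING_ATTRIBUTE"
BAD_NUMBER = "BAD_NUMBER"

_POLICY_ATTR = {
    "requireRespondentId": "require_respondent_id",
    "requireVisitCode": "require_visit_code",
    "requireVideoViewing": "require_video_viewing",
    "startVideoAutomatically": "start_video_automatically",
    "showComputedScore": "show_computed_score",
}

_METHOD_ELEMENT = {
    ScoreMethod.LOOKUP_TABLE: "lookupTable",
    ScoreMethod.SCORING_FUNCTION: "scoringFunction",
    ScoreMethod.CAT_TREE: "catTree",
}
_ELEMENT_METHOD = {v: k for k, v in _METHOD_ELEMENT.items()}


class _Collector:
    """Accumulates violations during a lenient parse."""

    def __init__(self) -> None:
        self.violations: list[Violation] = []

    def add(self, code: str, path: str, message: str) -> None:
        self.violations.append(Violation(code, path, message))


def _path(element: etree._Element) -> str:
    return element.getroottree().getpath(element)


def _parse_localized(
    parent: etree._Element, tag: str, collector: _Collector, attr: str | None = None
) -> LocalizedText:
    """Collect repeated localized *tag* children of *parent* into one text.

    The child without a ``lang`` attribute is the default; more than one
    default, or two children with the same tag for one locale, is an error.
    *attr* optionally names an attribute of *parent* that may carry the
    default text inline (the response ``label`` shortcut).
    """
    default: str | None = None
    variants: dict[str, str] = {}
    if attr is not None and parent.get(attr) is not None:
        default = parent.get(attr)
    for child in parent.findall(tag):
        text = child.text or ""
        lang = child.get("lang")
        if lang is None:
            if default is not None:
                collector.add(
                    MULTIPLE_DEFAULT_TEXT,
                    _path(child),
                    f"more than one default (lang-less) <{tag}> element",
                )
            else:
                default = text
        else:
            if lang in variants:
                collector.add(
                    DUPLICATE_LOCALE, _path(child), f"locale {lang!r} repeated for <{tag}>"
                )
            variants[lang] = text
    if default is None:
        if variants:
            # No explicit default: treat the first declared variant as the
            # fallback so resolution stays total.
            default = next(iter(variants.values()))
            collector.add(
                MISSING_CHILD,
                _path(parent),
                f"no default (lang-less) <{tag}> element",
            )
        else:
            default = ""
    return LocalizedText(default_text=default, variants=variants)


def _parse_policies(
    element: etree._Element | None, collector: _Collector, strict: bool
) -> InstrumentPolicies:
    policies = InstrumentPolicies()
    if element is None:
        return policies
    for policy in element.findall("policy"):
        key = policy.get("key")
        value = policy.get("value", policy.text or "")
        if key is None:
            collector.add(MISSING_ATTRIBUTE, _path(policy), "policy requires a 'key' attribute")
            continue
        if key not in POLICY_KEYS:
            if strict:
                collector.add(UNKNOWN_POLICY, _path(policy), f"unknown policy key {key!r}")
            continue
        if key == "serverSubmissionURL":
            policies.server_submission_url = value
        else:
            lowered = value.strip().lower()
            if lowered not in ("true", "false"):
                collector.add(
                    BAD_POLICY_VALUE,
                    _path(policy),
                    f"policy {key!r} must be 'true' or 'false', got {value!r}",
                )
                continue
            setattr(policies, _POLICY_ATTR[key], lowered == "true")
    return policies


def _parse_item(element: etree._Element, collector: _Collector) -> Item | None:
    item_id = element.get("id")
    number_text = element.get("number")
    if item_id is None or number_text is None:
        collector.add(
            MISSING_ATTRIBUTE, _path(element), "item requires 'id' and 'number' attributes"
        )
        return None
    try:
        number = int(number_text)
    except ValueError:
        collector.add(BAD_NUMBER, _path(element), f"item number {number_text!r} is not an integer")
        return None
    description = _parse_localized(element, "description", collector)
    media_el = element.find("media")
    media = media_el.text if media_el is not None else None
    category_el = element.find("scoringCategory")
    if category_el is None or not (category_el.text or "").strip():
        collector.add(
            MISSING_CHILD, _path(element), f"item {item_id!r} requires a <scoringCategory> child"
        )
        return None
    return Item(
        id=item_id,
        number=number,
        description=description,
        media=media,
        scoring_category=category_el.text.strip(),
    )


def _parse_items(element: etree._Element | None, collector: _Collector) -> list[Item]:
    items: list[Item] = []
    if element is None:
        return items
    for child in element.findall("item"):
        item = _parse_item(child, collector)
        if item is not None:
            items.append(item)
    return items


def _parse_category(element: etree._Element, collector: _Collector) -> ScoringCategory | None:
    cat_id = element.get("id")
    if cat_id is None:
        collector.add(MISSING_ATTRIBUTE, _path(element), "category requires an 'id' attribute")
        return None
    responses: list[ResponseOption] = []
    responses_el = element.find("responses")
    if responses_el is not None:
        for resp_el in responses_el.findall("response"):
            resp_id = resp_el.get("id")
            if resp_id is None:
                collector.add(
                    MISSING_ATTRIBUTE, _path(resp_el), "response requires an 'id' attribute"
                )
                continue
            label = _parse_localized(resp_el, "label", collector, attr="label")
            responses.append(ResponseOption(id=resp_id, label=label))
    mapping_el = element.find("mappingFunction")
    mapping = mapping_el.text.strip() if mapping_el is not None and mapping_el.text else None
    return ScoringCategory(id=cat_id, responses=responses, mapping_function=mapping)


def _parse_score_computation(
    element: etree._Element | None, collector: _Collector
) -> ScoreComputation | None:
    if element is None:
        return None
    found: list[tuple[ScoreMethod, str]] = []
    for tag, method in _ELEMENT_METHOD.items():
        child = element.find(tag)
        if child is not None:
            found.append((method, (child.text or "").strip()))
    if not found:
        collector.add(
            MISSING_CHILD,
            _path(element),
            "scoreComputation requires one of lookupTable, scoringFunction, catTree",
        )
        return None
    method, payload = found[0]
    comp = ScoreComputation(method=method)
    if method is ScoreMethod.LOOKUP_TABLE:
        comp.lookup_table_file = payload
    elif method is ScoreMethod.SCORING_FUNCTION:
        comp.scoring_expression = payload
    else:
        comp.cat_tree_file = payload
    if len(found) > 1:
        from .model import AMBIGUOUS_SCORE_METHOD

        collector.add(
            AMBIGUOUS_SCORE_METHOD,
            _path(element),
            "scoreComputation has more than one method payload",
        )
        # Keep the first payload but record the extras so validate() re-flags.
        for extra_method, extra_payload in found[1:]:
            if extra_method is ScoreMethod.LOOKUP_TABLE:
                comp.lookup_table_file = extra_payload
            elif extra_method is ScoreMethod.SCORING_FUNCTION:
                comp.scoring_expression = extra_payload
            else:
                comp.cat_tree_file = extra_payload
    return comp


def parse_instrument(document: str | bytes, strict: bool = True) -> Instrument:
    """Parse an instrument document into a fully linked :class:`Instrument`.

    Raises :class:`SchemaError` listing every violation found when *strict*
    (the default); with ``strict=False`` unknown policy keys are tolerated but
    genuine structural defects still raise.
    """
    instrument, violations = _parse_collecting(document, strict=strict)
    if violations:
        raise SchemaError(violations)
    return instrument


def collect_violations(document: str | bytes, strict: bool = True) -> list[Violation]:
    """Parse leniently and return every violation (empty list = valid)."""
    _, violations = _parse_collecting(document, strict=strict)
    return violations


def _parse_collecting(
    document: str | bytes, strict: bool = True
) -> tuple[Instrument, list[Violation]]:
    collector = _Collector()
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        return Instrument(), [Violation(XML_SYNTAX, "/", str(exc))]
    if root.tag != "instrument":
        return Instrument(), [
            Violation(WRONG_ROOT, "/", f"root element must be <instrument>, got <{root.tag}>")
        ]

    policies = _parse_policies(root.find("instrumentPolicies"), collector, strict)

    instructions = None
    instructions_el = root.find("instructions")
    if instructions_el is not None:
        text = _parse_localized(instructions_el, "instructionText", collector)
        practice = _parse_items(instructions_el.find("practiceItems"), collector)
        instructions = Instructions(instruction_text=text, practice_items=practice)

    items = _parse_items(root.find("items"), collector)

    categories: list[ScoringCategory] = []
    computation = None
    scoring_el = root.find("scoring")
    if scoring_el is not None:
        categories_el = scoring_el.find("categories")
        if categories_el is not None:
            for cat_el in categories_el.findall("category"):
                cat = _parse_category(cat_el, collector)
                if cat is not None:
                    categories.append(cat)
        computation = _parse_score_computation(scoring_el.find("scoreComputation"), collector)

    instrument = Instrument(
        policies=policies,
        instructions=instructions,
        items=items,
        categories=categories,
        score_computation=computation,
    )
    seen = {(v.code, v.path) for v in collector.violations}
    for violation in validate(instrument):
        if (violation.code, violation.path) not in seen:
            collector.violations.append(violation)
    return instrument, collector.violations


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _emit_localized(
    parent: etree._Element, tag: str, text: LocalizedText, inline_attr: str | None = None
) -> None:
    if inline_attr is not None and not text.variants:
        parent.set(inline_attr, text.default_text)
        return
    default = etree.SubElement(parent, tag)
    default.text = text.default_text
    for lang in sorted(text.variants):
        child = etree.SubElement(parent, tag)
        child.set("lang", lang)
        child.text = text.variants[lang]


def _emit_item(parent: etree._Element, item: Item) -> None:
    el = etree.SubElement(parent, "item")
    el.set("id", item.id)
    el.set("number", str(item.number))
    _emit_localized(el, "description", item.description)
    if item.media is not None:
        etree.SubElement(el, "media").text = item.media
    etree.SubElement(el, "scoringCategory").text = item.scoring_category


def serialize_instrument(instrument: Instrument) -> str:
    """Serialize to canonical UTF-8 XML text; deterministic for equal objects.

    Refuses (raises :class:`SchemaError`) if the instrument has violations,
    so a round-trip through :func:`parse_instrument` is always possible.
    Policies are emitted only when they differ from their defaults; items are
    ordered by number; locale variants sort by tag.
    """
    violations = validate(instrument)
    if violations:
        raise SchemaError(violations)

    root = etree.Element("instrument")

    pol = instrument.policies
    pol_el = etree.SubElement(root, "instrumentPolicies")
    for key in BOOLEAN_POLICY_KEYS:
        value = getattr(pol, _POLICY_ATTR[key])
        if value:
            policy = etree.SubElement(pol_el, "policy")
            policy.set("key", key)
            policy.set("value", "true")
    if pol.server_submission_url is not None:
        policy = etree.SubElement(pol_el, "policy")
        policy.set("key", "serverSubmissionURL")
        policy.set("value", pol.server_submission_url)

    if instrument.instructions is not None:
        instr_el = etree.SubElement(root, "instructions")
        _emit_localized(instr_el, "instructionText", instrument.instructions.instruction_text)
        if instrument.instructions.practice_items:
            practice_el = etree.SubElement(instr_el, "practiceItems")
            for item in sorted(instrument.instructions.practice_items, key=lambda i: i.number):
                _emit_item(practice_el, item)

    items_el = etree.SubElement(root, "items")
    for item in instrument.items_in_order():
        _emit_item(items_el, item)

    scoring_el = etree.SubElement(root, "scoring")
    categories_el = etree.SubElement(scoring_el, "categories")
    for cat in instrument.categories:
        cat_el = etree.SubElement(categories_el, "category")
        cat_el.set("id", cat.id)
        responses_el = etree.SubElement(cat_el, "responses")
        for resp in cat.responses:
            resp_el = etree.SubElement(responses_el, "response")
            resp_el.set("id", resp.id)
            _emit_localized(resp_el, "label", resp.label, inline_attr="label")
        if cat.mapping_function is not None:
            etree.SubElement(cat_el, "mappingFunction").text = cat.mapping_function
    comp = instrument.score_computation
    if comp is not None:
        comp_el = etree.SubElement(scoring_el, "scoreComputation")
        tag = _METHOD_ELEMENT[comp.method]
        payload = {
            ScoreMethod.LOOKUP_TABLE: comp.lookup_table_file,
            ScoreMethod.SCORING_FUNCTION: comp.scoring_expression,
            ScoreMethod.CAT_TREE: comp.cat_tree_file,
        }[comp.method]
        etree.SubElement(comp_el, tag).text = payload

    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def load_instrument(path: str | Path, strict: bool = True) -> Instrument:
    return parse_instrument(Path(path).read_bytes(), strict=strict)


def save_instrument(instrument: Instrument, path: str | Path) -> None:
    Path(path).write_text(serialize_instrument(instrument), encoding="utf-8")


def xsd_validate(document: str | bytes) -> list[str]:
    """Validate a document against the shipped canonical-form XSD.

    Returns a list of validator messages (empty = valid).  The XSD describes
    the canonical serialization order; order-shuffled but semantically valid
    documents should be parsed with :func:`parse_instrument` instead.
    """
    schema_text = (
        importlib.resources.files("catform").joinpath("data/instrument.xsd").read_bytes()
    )
    schema = etree.XMLSchema(etree.fromstring(schema_text))
    if isinstance(document, str):
        document = document.encode("utf-8")
    tree = etree.fromstring(document)
    schema.validate(tree)
    return [str(err) for err in schema.error_log]
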