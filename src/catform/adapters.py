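"""Presentation adapters: the pluggable front-end contract.

The engine never talks to a screen directly; it drives an adapter that knows
how to show instructions, play media, and collect a response.  Two adapters
ship here: a terminal adapter for interactive shell administration and a
scripted adapter that replays predetermined responses (for tests, batch
scoring and cohort simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

from .cat import CatTree
from .errors import CatformError
from .localization import resolve_text
from .model import Instrument, Item
from .scoring import LookupTable
from .session import (
    Clock,
    PresentationEvent,
    SessionRecord,
    complete_session,
    current_item,
    record_response,
    start_session,
    system_clock,
    visible_score,
)


class PresentationAdapter(Protocol):
    """What a front-end must implement to administer an instrument."""

    def show_instructions(self, text: str) -> None: ...

    def ask(self, item: Item, labels: Sequence[tuple[str, str]], practice: bool) -> str:
        """Present one item; return the chosen response id.

        ``labels`` pairs each legal response id with its localized label.
        """

    def show_score(self, score: float) -> None: ...


@dataclass
class ScriptedAdapter:
    """Replays a fixed response-id sequence; records what it was shown."""

    responses: list[str]
    shown: list[str] = field(default_factory=list)
    _cursor: int = 0

    def show_instructions(self, text: str) -> None:
        self.shown.append(f"instructions: {text}")

    def ask(self, item: Item, labels: Sequence[tuple[str, str]], practice: bool) -> str:
        self.shown.append(f"{'practice ' if practice else ''}item {item.id}")
        if practice:
            return labels[0][0]
        if self._cursor >= len(self.responses):
            raise CatformError("scripted adapter ran out of responses")
        response = self.responses[self._cursor]
        self._cursor += 1
        return response

    def show_score(self, score: float) -> None:
        self.shown.append(f"score: {score}")


@dataclass
class TerminalAdapter:
    """Interactive shell front-end (used by the ``administer`` command)."""

    input_fn: Callable[[str], str] = input
    print_fn: Callable[[str], None] = print

    def show_instructions(self, text: str) -> None:
        self.print_fn(text)

    def ask(self, item: Item, labels: Sequence[tuple[str, str]], practice: bool) -> str:
        prefix = "[practice] " if practice else ""
        self.print_fn(f"{prefix}{item.description.default_text}")
        for index, (_, label) in enumerate(labels):
            self.print_fn(f"  {index}: {label}")
        while True:
            raw = self.input_fn("response number: ").strip()
            if raw.isdigit() and int(raw) < len(labels):
                return labels[int(raw)][0]
            self.print_fn("please enter one of the listed numbers")

    def show_score(self, score: float) -> None:
        self.print_fn(f"your score: {score:.3f}")


def administer(
    instrument: Instrument,
    adapter: PresentationAdapter,
    session_id: str,
    clock: Clock = system_clock,
    *,
    respondent_id: str | None = None,
    visit_code: str | None = None,
    locale: str | None = None,
    table: LookupTable | None = None,
    tree: CatTree | None = None,
) -> SessionRecord:
    """Run one full session through an adapter: instructions and practice
    items first (unscored), then every test item in engine order, then
    completion, scoring, and — policy permitting — score display."""
    session = start_session(
        instrument,
        session_id,
        clock,
        respondent_id=respondent_id,
        visit_code=visit_code,
        locale=locale,
    )
    if instrument.instructions is not None:
        adapter.show_instructions(
            resolve_text(instrument.instructions.instruction_text, locale)
        )
        for practice_item in sorted(
            instrument.instructions.practice_items, key=lambda i: i.number
        ):
            labels = _labels(instrument, practice_item, locale)
            adapter.ask(practice_item, labels, practice=True)

    while (item := current_item(instrument, session, tree)) is not None:
        labels = _labels(instrument, item, locale)
        response_id = adapter.ask(item, labels, practice=False)
        events = [PresentationEvent(kind="media_completed", item_id=item.id)]
        record_response(
            instrument, session, item.id, response_id, clock, events=events, tree=tree
        )

    complete_session(instrument, session, clock, table=table, tree=tree)
    score = visible_score(instrument, session)
    if score is not None:
        adapter.show_score(score)
    return session


def _labels(
    instrument: Instrument, item: Item, locale: str | None
) -> list[tuple[str, str]]:
    category = instrument.category(item.scoring_category)
    return [(resp.id, resolve_text(resp.label, locale)) for resp in category.responses]
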