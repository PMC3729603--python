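"""Session lifecycle: administering an instrument, enforcing policies,
persisting results, exporting a single table, and queueing server submission.

This is the engine behind any presentation front-end.  A session walks the
instrument's items strictly in order (or down the adaptive tree for a
tree-scored instrument), validates each response against the item's category,
stamps everything with an injectable clock, and computes the overall score at
completion according to the instrument's score computation.  Completed
sessions can be exported as one CSV row each and queued for at-least-once
delivery to a collection server.
"""

from __future__ import annotations

import datetime as dt
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .cat import CatTree, TraversalState, next_item, start_traversal
from .errors import CatformError, PolicyError, SessionStateError, StoreError
from .expressions import parse_expression
from .model import Instrument, Item, ScoreMethod
from .scoring import (
    LookupTable,
    ResponsePattern,
    map_response,
    score_function,
    score_lookup,
)

Clock = Callable[[], dt.datetime]


def system_clock() -> dt.datetime:
    return dt.datetime.now(dt.timezone.utc)


IN_PROGRESS = "in_progress"
COMPLETED = "completed"
DISCARDED = "discarded"


@dataclass
class PresentationEvent:
    """Something the presentation layer reports back to the engine."""

    kind: str  # media_started | media_completed | response_selected
    item_id: str
    payload: dict = field(default_factory=dict)


@dataclass
class RecordedResponse:
    item_id: str
    response_id: str
    value: float
    timestamp: dt.datetime


@dataclass
class SessionRecord:
    """One participant's run of an instrument."""

    session_id: str
    locale: str | None = None
    respondent_id: str | None = None
    visit_code: str | None = None
    responses: list[RecordedResponse] = field(default_factory=list)
    start: dt.datetime | None = None
    end: dt.datetime | None = None
    score: float | None = None
    status: str = IN_PROGRESS
    submitted: bool = False

    @property
    def duration_s(self) -> int | None:
        if self.start is None or self.end is None:
            return None
        return int((self.end - self.start).total_seconds())


def start_session(
    instrument: Instrument,
    session_id: str,
    clock: Clock = system_clock,
    *,
    respondent_id: str | None = None,
    visit_code: str | None = None,
    locale: str | None = None,
) -> SessionRecord:
    """Open a session, enforcing identifier policies up front.

    Practice items (if any) are presented by the adapter but never recorded
    here — only scored test items enter ``responses``.
    """
    policies = instrument.policies
    if policies.require_respondent_id and not respondent_id:
        raise PolicyError("REQUIRE_RESPONDENT_ID", "a respondent id is required before starting")
    if policies.require_visit_code and not visit_code:
        raise PolicyError("REQUIRE_VISIT_CODE", "a visit code is required before starting")
    return SessionRecord(
        session_id=session_id,
        locale=locale,
        respondent_id=respondent_id,
        visit_code=visit_code,
        start=clock(),
    )


def _tree_state(session: SessionRecord, tree: CatTree) -> TraversalState:
    """Replay the session's responses down the tree (bounded by tree depth)."""
    state = start_traversal(tree)
    for resp in session.responses:
        state = next_item(tree, state, affirmative=resp.value > 0)
    return state


def current_item(
    instrument: Instrument, session: SessionRecord, tree: CatTree | None = None
) -> Item | None:
    """The item the participant should answer next; None when all are done."""
    if tree is not None:
        state = _tree_state(session, tree)
        if state.finished:
            return None
        return instrument.item(state.current_item)
    ordered = instrument.items_in_order()
    if len(session.responses) >= len(ordered):
        return None
    return ordered[len(session.responses)]


def record_response(
    instrument: Instrument,
    session: SessionRecord,
    item_id: str,
    response_id: str,
    clock: Clock = system_clock,
    events: Sequence[PresentationEvent] = (),
    tree: CatTree | None = None,
) -> SessionRecord:
    """Validate and record one response; the cursor advances by one item.

    Items must be answered strictly in presentation order; under the
    requireVideoViewing policy a ``media_completed`` event for the item must
    have been reported before the response is accepted.
    """
    if session.status != IN_PROGRESS:
        raise SessionStateError(f"cannot record a response on a {session.status} session")
    expected = current_item(instrument, session, tree)
    if expected is None:
        raise SessionStateError("all items have been answered")
    if item_id != expected.id:
        raise SessionStateError(
            f"out-of-order response: expected item {expected.id!r}, got {item_id!r}"
        )
    if instrument.policies.require_video_viewing:
        completed = any(
            ev.kind == "media_completed" and ev.item_id == item_id for ev in events
        )
        if not completed:
            raise PolicyError(
                "REQUIRE_VIDEO_VIEWING",
                f"the media for item {item_id!r} must play to completion before responding",
            )
    category = instrument.category(expected.scoring_category)
    value = map_response(category, response_id)  # raises on unknown response id
    session.responses.append(
        RecordedResponse(item_id=item_id, response_id=response_id, value=value, timestamp=clock())
    )
    return session


def session_pattern(instrument: Instrument, session: SessionRecord) -> ResponsePattern:
    """The session's mapped values in item-number order (linear instruments)."""
    by_item = {resp.item_id: resp.value for resp in session.responses}
    values = tuple(by_item[item.id] for item in instrument.items_in_order() if item.id in by_item)
    return ResponsePattern(values=values)


def complete_session(
    instrument: Instrument,
    session: SessionRecord,
    clock: Clock = system_clock,
    *,
    table: LookupTable | None = None,
    tree: CatTree | None = None,
) -> SessionRecord:
    """Close a fully answered session and compute its score if configured.

    Scoring follows the instrument's score computation: exact lookup of the
    response pattern, runtime evaluation of the scoring expression on the
    pattern sum, or the stored score at the adaptive tree's leaf.  An
    instrument without a score computation completes with no score.
    """
    if session.status != IN_PROGRESS:
        raise SessionStateError(f"cannot complete a {session.status} session")
    if current_item(instrument, session, tree) is not None:
        raise SessionStateError("session has unanswered items")
    comp = instrument.score_computation
    if comp is not None:
        if comp.method is ScoreMethod.LOOKUP_TABLE:
            if table is None:
                raise CatformError("instrument scores by lookup table but none was provided")
            session.score = score_lookup(table, session_pattern(instrument, session))
        elif comp.method is ScoreMethod.SCORING_FUNCTION:
            expr = parse_expression(comp.scoring_expression or "")
            session.score = score_function(expr, session_pattern(instrument, session))
        elif comp.method is ScoreMethod.CAT_TREE:
            if tree is None:
                raise CatformError("instrument scores by CAT tree but none was provided")
            session.score = _tree_state(session, tree).score
    session.end = clock()
    session.status = COMPLETED
    return session


def visible_score(instrument: Instrument, session: SessionRecord) -> float | None:
    """The score the presentation layer may show — gated by showComputedScore."""
    if not instrument.policies.show_computed_score:
        return None
    return session.score


def discard_session(session: SessionRecord) -> SessionRecord:
    """Abandon an in-progress session; it is kept on file but never exported
    or submitted."""
    if session.status != IN_PROGRESS:
        raise SessionStateError(f"cannot discard a {session.status} session")
    session.status = DISCARDED
    return session


# ---------------------------------------------------------------------------
# Store: a single JSON document file with timestamped backups.
# ---------------------------------------------------------------------------

_TS = "%Y-%m-%dT%H:%M:%S%z"


def _session_to_dict(session: SessionRecord) -> dict:
    return {
        "session_id": session.session_id,
        "locale": session.locale,
        "respondent_id": session.respondent_id,
        "visit_code": session.visit_code,
        "start": session.start.strftime(_TS) if session.start else None,
        "end": session.end.strftime(_TS) if session.end else None,
        "score": session.score,
        "status": session.status,
        "submitted": session.submitted,
        "responses": [
            {
                "item_id": r.item_id,
                "response_id": r.response_id,
                "value": r.value,
                "timestamp": r.timestamp.strftime(_TS),
            }
            for r in session.responses
        ],
    }


def _session_from_dict(data: dict) -> SessionRecord:
    def ts(text: str | None) -> dt.datetime | None:
        return dt.datetime.strptime(text, _TS) if text else None

    return SessionRecord(
        session_id=data["session_id"],
        locale=data.get("locale"),
        respondent_id=data.get("respondent_id"),
        visit_code=data.get("visit_code"),
        start=ts(data.get("start")),
        end=ts(data.get("end")),
        score=data.get("score"),
        status=data.get("status", IN_PROGRESS),
        submitted=bool(data.get("submitted", False)),
        responses=[
            RecordedResponse(
                item_id=r["item_id"],
                response_id=r["response_id"],
                value=float(r["value"]),
                timestamp=ts(r["timestamp"]),
            )
            for r in data.get("responses", [])
        ],
    )


def persist_store(
    sessions: Iterable[SessionRecord], path: str | Path, clock: Clock = system_clock
) -> None:
    """Write all sessions to *path*, first backing up the previous store.

    The backup is a sibling file tagged with the clock's timestamp (plus a
    counter when two saves share a second), so no prior state is ever lost.
    """
    path = Path(path)
    if path.exists():
        stamp = clock().strftime("%Y%m%dT%H%M%S")
        backup = path.with_name(f"{path.name}.bak-{stamp}")
        counter = 0
        while backup.exists():
            counter += 1
            backup = path.with_name(f"{path.name}.bak-{stamp}-{counter}")
        shutil.copy2(path, backup)
    payload = {"sessions": [_session_to_dict(s) for s in sessions]}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _newest_backup(path: Path) -> str | None:
    backups = sorted(path.parent.glob(path.name + ".bak-*"))
    return str(backups[-1]) if backups else None


def load_store(path: str | Path) -> list[SessionRecord]:
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
        return [_session_from_dict(item) for item in data["sessions"]]
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise StoreError(
            f"session store {path} is corrupt: {exc}", backup=_newest_backup(path)
        ) from exc


# ---------------------------------------------------------------------------
# Export: one CSV row per completed session.
# ---------------------------------------------------------------------------


def export_table(
    sessions: Iterable[SessionRecord], instrument: Instrument, path: str | Path
) -> int:
    """Write the single analysis table; returns the number of rows.

    Columns: session_id, respondent_id, visit_code, start (ISO 8601),
    duration_s, one column per item id (mapped value; blank if the adaptive
    path skipped the item), score.  Discarded and in-progress sessions are
    excluded.
    """
    items = [item.id for item in instrument.items_in_order()]
    columns = ["session_id", "respondent_id", "visit_code", "start", "duration_s"] + items + ["score"]
    rows = []
    for session in sessions:
        if session.status != COMPLETED:
            continue
        by_item = {r.item_id: r.value for r in session.responses}
        row = {
            "session_id": session.session_id,
            "respondent_id": session.respondent_id,
            "visit_code": session.visit_code,
            "start": session.start.strftime(_TS) if session.start else None,
            "duration_s": session.duration_s,
            "score": session.score,
        }
        for item_id in items:
            row[item_id] = by_item.get(item_id)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False)
    return len(rows)


# ---------------------------------------------------------------------------
# Submission queue: at-least-once delivery to the collection server.
# ---------------------------------------------------------------------------

Transport = Callable[[str, dict], bool]


@dataclass
class SubmissionAttempt:
    session_id: str
    timestamp: dt.datetime
    ok: bool
    detail: str = ""


@dataclass
class SubmissionQueue:
    """Pending completed sessions awaiting acknowledged server delivery.

    A session leaves the queue only when the transport reports success;
    failures stay queued with the attempt logged, so delivery is
    at-least-once across flushes.
    """

    pending: list[str] = field(default_factory=list)
    attempts: list[SubmissionAttempt] = field(default_factory=list)


def submission_payload(instrument: Instrument, session: SessionRecord) -> dict:
    """The documented wire format: one self-contained session document."""
    return {"format": "catform-session", "version": 1, "session": _session_to_dict(session)}


def enqueue_submission(
    queue: SubmissionQueue, instrument: Instrument, session: SessionRecord
) -> bool:
    """Queue a completed session for delivery; no-op without a submission URL."""
    if instrument.policies.server_submission_url is None:
        return False
    if session.status != COMPLETED:
        raise SessionStateError("only completed sessions can be submitted")
    if session.session_id not in queue.pending and not session.submitted:
        queue.pending.append(session.session_id)
    return True


def flush_queue(
    queue: SubmissionQueue,
    instrument: Instrument,
    sessions: dict[str, SessionRecord],
    transport: Transport,
    clock: Clock = system_clock,
) -> dict[str, bool]:
    """Attempt delivery of every pending session; returns per-session outcomes.

    Transport failures (False return or exception) are recorded in the
    attempt log and the session stays pending; acknowledged sends are marked
    submitted and dequeued.
    """
    url = instrument.policies.server_submission_url
    if url is None:
        return {}
    outcomes: dict[str, bool] = {}
    still_pending: list[str] = []
    for session_id in queue.pending:
        session = sessions[session_id]
        try:
            ok = bool(transport(url, submission_payload(instrument, session)))
            detail = "" if ok else "transport returned failure"
        except Exception as exc:  # failures must never reach the participant flow
            ok, detail = False, str(exc)
        queue.attempts.append(
            SubmissionAttempt(session_id=session_id, timestamp=clock(), ok=ok, detail=detail)
        )
        outcomes[session_id] = ok
        if ok:
            session.submitted = True
        else:
            still_pending.append(session_id)
    queue.pending = still_pending
    return outcomes
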