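"""Administer a session through the engine: policies, scoring, export, submission.

Uses the scripted adapter (the test/batch front-end) to run one participant
through a lookup-table-scored instrument with a respondent-id requirement,
then exports the single analysis table and demonstrates at-least-once
server submission with a transport that fails on its first attempt.
"""

import tempfile
from pathlib import Path

from catform import (
    FixtureConfig,
    InstrumentPolicies,
    ScoreMethod,
    ScriptedAdapter,
    SubmissionQueue,
    administer,
    build_instrument,
    build_lookup_table,
    enqueue_submission,
    export_table,
    flush_queue,
    generate_item_bank,
)

config = FixtureConfig(
    seed=4,
    items=3,
    responses=2,
    policies=InstrumentPolicies(
        require_respondent_id=True,
        show_computed_score=True,
        server_submission_url="https://collect.example.org/api",
    ),
    score_method=ScoreMethod.LOOKUP_TABLE,
    score_payload="scores.tsv",
)
instrument = build_instrument(config)
bank = generate_item_bank(config)
table = build_lookup_table(instrument, bank)

adapter = ScriptedAdapter(responses=["yes", "no", "yes"])
session = administer(
    instrument, adapter, session_id="demo-1", respondent_id="participant-07", table=table
)
print(f"session {session.session_id}: status={session.status}, "
      f"score={session.score:+.4f}, duration={session.duration_s}s")

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "table.csv"
    rows = export_table([session], instrument, out)
    print(f"exported {rows} row(s):")
    print(out.read_text().strip())

queue = SubmissionQueue()
enqueue_submission(queue, instrument, session)
attempts = {"n": 0}

def flaky_transport(url, payload):
    attempts["n"] += 1
    return attempts["n"] > 1  # network down on the first try

print("flush 1:", flush_queue(queue, instrument, {"demo-1": session}, flaky_transport))
print("flush 2:", flush_queue(queue, instrument, {"demo-1": session}, flaky_transport))
print("submitted:", session.submitted, "| pending:", queue.pending)
# The failed first delivery stays queued with its attempt logged; the second
# flush succeeds, marks the session submitted, and empties the queue.
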