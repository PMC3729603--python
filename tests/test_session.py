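"""Session lifecycle, policy enforcement, persistence, export, submission."""

import json

import pytest

from catform import (
    FixtureConfig,
    InstrumentPolicies,
    PolicyError,
    PresentationEvent,
    ScoreMethod,
    ScriptedAdapter,
    SessionStateError,
    StoreError,
    SubmissionQueue,
    administer,
    build_instrument,
    build_lookup_table,
    build_tree,
    complete_session,
    current_item,
    discard_session,
    enqueue_submission,
    export_table,
    flush_queue,
    generate_item_bank,
    load_store,
    persist_store,
    record_response,
    session_pattern,
    start_session,
    score_lookup,
    submission_payload,
    visible_score,
)


def make_instrument(**policy_kwargs):
    config = FixtureConfig(
        seed=4,
        items=3,
        responses=2,
        policies=InstrumentPolicies(**policy_kwargs),
        with_instructions=True,
    )
    return build_instrument(config)


def answer_all(instrument, session, clock, answers=("yes", "yes", "no")):
    for item, response in zip(instrument.items_in_order(), answers):
        record_response(instrument, session, item.id, response, clock)
    return session


class TestStartAndPolicies:
    def test_starts_without_identifiers_when_policies_allow(self, fixed_clock):
        session = start_session(make_instrument(), "s1", fixed_clock)
        assert session.status == "in_progress"
        assert session.start is not None

    def test_required_respondent_id_enforced(self, fixed_clock):
        instrument = make_instrument(require_respondent_id=True)
        with pytest.raises(PolicyError, match="REQUIRE_RESPONDENT_ID"):
            start_session(instrument, "s1", fixed_clock)
        session = start_session(instrument, "s1", fixed_clock, respondent_id="p01")
        assert session.respondent_id == "p01"

    def test_required_visit_code_enforced(self, fixed_clock):
        instrument = make_instrument(require_visit_code=True)
        with pytest.raises(PolicyError, match="REQUIRE_VISIT_CODE"):
            start_session(instrument, "s1", fixed_clock, respondent_id="p01")
        start_session(instrument, "s1", fixed_clock, visit_code="v1")

    def test_video_viewing_gate(self, fixed_clock):
        instrument = make_instrument(require_video_viewing=True)
        session = start_session(instrument, "s1", fixed_clock)
        item = instrument.items_in_order()[0]
        with pytest.raises(PolicyError, match="REQUIRE_VIDEO_VIEWING"):
            record_response(instrument, session, item.id, "yes", fixed_clock, events=[])
        record_response(
            instrument,
            session,
            item.id,
            "yes",
            fixed_clock,
            events=[PresentationEvent(kind="media_completed", item_id=item.id)],
        )
        assert len(session.responses) == 1

    def test_without_video_policy_no_event_is_needed(self, fixed_clock):
        instrument = make_instrument()
        session = start_session(instrument, "s1", fixed_clock)
        item = instrument.items_in_order()[0]
        record_response(instrument, session, item.id, "yes", fixed_clock)
        assert len(session.responses) == 1

    def test_score_display_gated_by_policy(self, fixed_clock):
        shown = make_instrument(show_computed_score=True)
        hidden = make_instrument(show_computed_score=False)
        s1 = start_session(shown, "a", fixed_clock)
        answer_all(shown, s1, fixed_clock)
        complete_session(shown, s1, fixed_clock)
        s1.score = 1.25
        s2 = start_session(hidden, "b", fixed_clock)
        answer_all(hidden, s2, fixed_clock)
        complete_session(hidden, s2, fixed_clock)
        s2.score = 1.25
        assert visible_score(shown, s1) == 1.25
        assert visible_score(hidden, s2) is None


class TestRecording:
    def test_cursor_advances_in_item_number_order(self, fixed_clock):
        instrument = make_instrument()
        session = start_session(instrument, "s1", fixed_clock)
        first = current_item(instrument, session)
        assert first.number == 0
        record_response(instrument, session, first.id, "no", fixed_clock)
        assert current_item(instrument, session).number == 1

    def test_out_of_order_response_rejected(self, fixed_clock):
        instrument = make_instrument()
        session = start_session(instrument, "s1", fixed_clock)
        third = instrument.items_in_order()[2]
        with pytest.raises(SessionStateError, match="out-of-order"):
            record_response(instrument, session, third.id, "no", fixed_clock)

    def test_unknown_response_id_rejected(self, fixed_clock):
        instrument = make_instrument()
        session = start_session(instrument, "s1", fixed_clock)
        item = instrument.items_in_order()[0]
        with pytest.raises(Exception, match="zz"):
            record_response(instrument, session, item.id, "zz", fixed_clock)
        assert session.responses == []

    def test_practice_items_are_never_recorded(self, fixed_clock):
        instrument = make_instrument()
        adapter = ScriptedAdapter(responses=["yes", "no", "yes"])
        session = administer(instrument, adapter, "s1", fixed_clock)
        assert len(session.responses) == 3  # test items only
        assert any(s.startswith("practice item") for s in adapter.shown)
        recorded_ids = {r.item_id for r in session.responses}
        assert "p000" not in recorded_ids


class TestCompletion:
    def test_completion_without_score_computation(self, fixed_clock):
        instrument = make_instrument()
        session = start_session(instrument, "s1", fixed_clock)
        answer_all(instrument, session, fixed_clock)
        complete_session(instrument, session, fixed_clock)
        assert session.status == "completed"
        assert session.score is None
        assert session.end is not None

    def test_incomplete_session_cannot_complete(self, fixed_clock):
        instrument = make_instrument()
        session = start_session(instrument, "s1", fixed_clock)
        with pytest.raises(SessionStateError, match="unanswered"):
            complete_session(instrument, session, fixed_clock)

    def test_duration_comes_from_the_injected_clock(self, fixed_clock):
        instrument = make_instrument()
        session = start_session(instrument, "s1", fixed_clock)  # t+1
        answer_all(instrument, session, fixed_clock)  # t+2..t+4
        complete_session(instrument, session, fixed_clock)  # t+5
        assert session.duration_s == 4

    def test_lookup_scored_session_matches_direct_lookup(self, fixed_clock):
        config = FixtureConfig(
            seed=4, items=3, responses=2, with_instructions=False,
            score_method=ScoreMethod.LOOKUP_TABLE, score_payload="scores.tsv",
        )
        instrument = build_instrument(config)
        bank = generate_item_bank(config)
        table = build_lookup_table(instrument, bank)
        session = start_session(instrument, "s1", fixed_clock)
        answer_all(instrument, session, fixed_clock, answers=("yes", "no", "yes"))
        complete_session(instrument, session, fixed_clock, table=table)
        assert session.score == score_lookup(table, session_pattern(instrument, session))

    def test_scoring_function_applies_to_pattern_sum(self, fixed_clock):
        config = FixtureConfig(
            seed=4, items=3, responses=2, with_instructions=False,
            score_method=ScoreMethod.SCORING_FUNCTION, score_payload="value / 3",
        )
        instrument = build_instrument(config)
        session = start_session(instrument, "s1", fixed_clock)
        answer_all(instrument, session, fixed_clock, answers=("yes", "yes", "yes"))
        complete_session(instrument, session, fixed_clock)
        assert session.score == pytest.approx(1.0)

    def test_cat_tree_session_scores_at_the_leaf(self, fixed_clock):
        config = FixtureConfig(
            seed=9, items=6, responses=2, with_instructions=False,
            score_method=ScoreMethod.CAT_TREE, score_payload="tree.tsv",
        )
        instrument = build_instrument(config)
        bank = generate_item_bank(config)
        tree = build_tree(bank, 4)
        session = start_session(instrument, "s1", fixed_clock)
        answers = [True, False, True, True]
        while (item := current_item(instrument, session, tree)) is not None:
            response = "yes" if answers[len(session.responses)] else "no"
            record_response(instrument, session, item.id, response, fixed_clock, tree=tree)
        complete_session(instrument, session, fixed_clock, tree=tree)
        assert len(session.responses) == 4  # adaptive length, not bank size
        from catform import start_traversal, next_item as tree_next

        state = start_traversal(tree)
        for a in answers:
            state = tree_next(tree, state, affirmative=a)
        assert session.score == state.score


class TestDiscard:
    def test_discarded_sessions_are_excluded_from_export(self, fixed_clock, tmp_path):
        instrument = make_instrument()
        keep = start_session(instrument, "keep", fixed_clock)
        answer_all(instrument, keep, fixed_clock)
        complete_session(instrument, keep, fixed_clock)
        drop = start_session(instrument, "drop", fixed_clock)
        discard_session(drop)
        assert drop.status == "discarded"
        out = tmp_path / "table.csv"
        assert export_table([keep, drop], instrument, out) == 1

    def test_cannot_discard_a_completed_session(self, fixed_clock):
        instrument = make_instrument()
        session = start_session(instrument, "s", fixed_clock)
        answer_all(instrument, session, fixed_clock)
        complete_session(instrument, session, fixed_clock)
        with pytest.raises(SessionStateError):
            discard_session(session)

    def test_discarded_status_survives_store_round_trip(self, fixed_clock, tmp_path):
        instrument = make_instrument()
        session = start_session(instrument, "s", fixed_clock)
        discard_session(session)
        path = tmp_path / "store.json"
        persist_store([session], path, fixed_clock)
        assert load_store(path)[0].status == "discarded"


class TestStore:
    def make_sessions(self, fixed_clock, n=3):
        instrument = make_instrument()
        sessions = []
        for i in range(n):
            s = start_session(instrument, f"s{i}", fixed_clock, respondent_id=f"r{i}")
            answer_all(instrument, s, fixed_clock)
            complete_session(instrument, s, fixed_clock)
            sessions.append(s)
        return instrument, sessions

    def test_round_trip_identity(self, fixed_clock, tmp_path):
        _, sessions = self.make_sessions(fixed_clock)
        path = tmp_path / "store.json"
        persist_store(sessions, path, fixed_clock)
        assert load_store(path) == sessions

    def test_second_save_backs_up_the_first(self, fixed_clock, tmp_path):
        _, sessions = self.make_sessions(fixed_clock)
        path = tmp_path / "store.json"
        persist_store(sessions[:1], path, fixed_clock)
        first_bytes = path.read_bytes()
        persist_store(sessions, path, fixed_clock)
        backups = list(tmp_path.glob("store.json.bak-*"))
        assert len(backups) == 1
        assert backups[0].read_bytes() == first_bytes
        assert load_store(path) == sessions

    def test_corrupt_store_names_newest_backup(self, fixed_clock, tmp_path):
        _, sessions = self.make_sessions(fixed_clock)
        path = tmp_path / "store.json"
        persist_store(sessions, path, fixed_clock)
        persist_store(sessions, path, fixed_clock)  # creates a backup
        path.write_text("{ truncated", encoding="utf-8")
        with pytest.raises(StoreError) as err:
            load_store(path)
        assert err.value.backup is not None
        assert load_store(err.value.backup) == sessions

    def test_recorded_responses_survive_crash_reload(self, fixed_clock, tmp_path):
        instrument = make_instrument()
        session = start_session(instrument, "s", fixed_clock)
        item = instrument.items_in_order()[0]
        record_response(instrument, session, item.id, "yes", fixed_clock)
        path = tmp_path / "store.json"
        persist_store([session], path, fixed_clock)
        # crash: the in-memory object is gone; reload and continue
        [reloaded] = load_store(path)
        assert reloaded.responses[0].response_id == "yes"
        for it, resp in zip(instrument.items_in_order()[1:], ("no", "no")):
            record_response(instrument, reloaded, it.id, resp, fixed_clock)
        complete_session(instrument, reloaded, fixed_clock)
        assert reloaded.status == "completed"


class TestExport:
    def test_header_only_for_zero_completed_sessions(self, fixed_clock, tmp_path):
        instrument = make_instrument()
        out = tmp_path / "t.csv"
        assert export_table([], instrument, out) == 0
        header = out.read_text().splitlines()[0]
        assert header.split(",")[:5] == ["session_id", "respondent_id", "visit_code", "start", "duration_s"]
        assert header.split(",")[-1] == "score"

    def test_one_row_per_completed_session(self, fixed_clock, tmp_path):
        instrument, sessions = TestStore().make_sessions(fixed_clock, n=2)
        extra = start_session(instrument, "x", fixed_clock)
        discard_session(extra)
        out = tmp_path / "t.csv"
        assert export_table(sessions + [extra], instrument, out) == 2
        assert len(out.read_text().splitlines()) == 3

    def test_item_columns_in_number_order(self, fixed_clock, tmp_path):
        instrument, sessions = TestStore().make_sessions(fixed_clock, n=1)
        out = tmp_path / "t.csv"
        export_table(sessions, instrument, out)
        header = out.read_text().splitlines()[0].split(",")
        item_cols = header[5:-1]
        assert item_cols == [it.id for it in instrument.items_in_order()]


class TestSubmission:
    def completed(self, fixed_clock, url="https://collect.example.org/api"):
        instrument = make_instrument()
        instrument.policies.server_submission_url = url
        session = start_session(instrument, "s1", fixed_clock)
        answer_all(instrument, session, fixed_clock)
        complete_session(instrument, session, fixed_clock)
        return instrument, session

    def test_failed_transport_keeps_session_queued_with_attempt_logged(self, fixed_clock):
        instrument, session = self.completed(fixed_clock)
        queue = SubmissionQueue()
        enqueue_submission(queue, instrument, session)

        def failing(url, payload):
            raise ConnectionError("network down")

        outcomes = flush_queue(queue, instrument, {"s1": session}, failing, fixed_clock)
        assert outcomes == {"s1": False}
        assert queue.pending == ["s1"]
        assert len(queue.attempts) == 1 and not queue.attempts[0].ok
        assert session.submitted is False

    def test_success_on_second_flush_dequeues_and_marks_submitted(self, fixed_clock):
        instrument, session = self.completed(fixed_clock)
        queue = SubmissionQueue()
        enqueue_submission(queue, instrument, session)
        calls = {"n": 0}

        def flaky(url, payload):
            calls["n"] += 1
            if calls["n"] == 1:
                return False
            assert url == instrument.policies.server_submission_url
            assert payload["session"]["session_id"] == "s1"
            return True

        flush_queue(queue, instrument, {"s1": session}, flaky, fixed_clock)
        assert queue.pending == ["s1"]
        flush_queue(queue, instrument, {"s1": session}, flaky, fixed_clock)
        assert queue.pending == []
        assert session.submitted is True
        assert [a.ok for a in queue.attempts] == [False, True]

    def test_enqueue_is_a_noop_without_submission_url(self, fixed_clock):
        instrument = make_instrument()
        session = start_session(instrument, "s1", fixed_clock)
        answer_all(instrument, session, fixed_clock)
        complete_session(instrument, session, fixed_clock)
        queue = SubmissionQueue()
        assert enqueue_submission(queue, instrument, session) is False
        assert queue.pending == []

    def test_payload_is_a_self_contained_json_document(self, fixed_clock):
        instrument, session = self.completed(fixed_clock)
        payload = submission_payload(instrument, session)
        text = json.dumps(payload)  # must be JSON-serializable
        decoded = json.loads(text)
        assert decoded["format"] == "catform-session"
        assert decoded["session"]["responses"][0]["item_id"] == "i000"
        assert decoded["session"]["status"] == "completed"
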