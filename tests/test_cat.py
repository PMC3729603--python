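"""Pre-computed adaptive-testing trees: structure, traversal, files, oracle."""

import itertools

import numpy as np
import pytest

from catform import (
    FixtureConfig,
    IntractableError,
    ItemParameters,
    SessionStateError,
    TreeFileError,
    build_tree,
    count_nodes,
    deserialize_tree,
    generate_item_bank,
    next_item,
    serialize_tree,
    start_traversal,
    validate_tree,
)
from catform.cat import DUPLICATE_ITEM_ON_PATH, UNKNOWN_ITEM
from conftest import eap_oracle, online_cat_oracle


@pytest.fixture(scope="module")
def bank8():
    return generate_item_bank(FixtureConfig(seed=8, items=8, responses=2))


@pytest.fixture(scope="module")
def tree4(bank8):
    return build_tree(bank8, 4)


class TestStructure:
    @pytest.mark.parametrize("n", [1, 2, 3, 5])
    def test_node_count_formula(self, bank8, n):
        assert count_nodes(build_tree(bank8, n)) == 2 ** (n + 1) - 1

    def test_root_carries_item_but_no_score(self, tree4):
        assert tree4.root.item_id is not None
        assert tree4.root.score is None and tree4.root.se is None

    def test_every_non_root_node_carries_score_and_se(self, tree4, bank8):
        assert validate_tree(tree4, bank8) == []

    def test_root_item_maximizes_information_at_prior_mean(self):
        bank = [
            ItemParameters("lo", 1.0, (-1.0,)),
            ItemParameters("mid", 2.0, (0.0,)),
            ItemParameters("hi", 1.0, (1.0,)),
        ]
        tree = build_tree(bank, 2)
        # brute force: a^2 p(1-p) at theta=0 is 1.0 for "mid", ~0.2 for others
        assert tree.root.item_id == "mid"

    def test_leaf_scores_are_exactly_the_path_eap(self, tree4, bank8):
        from catform import eap_estimate

        by_id = {p.item_id: p for p in bank8}
        for responses in itertools.product([0, 1], repeat=4):
            state = start_traversal(tree4)
            path_items = []
            for r in responses:
                path_items.append(state.current_item)
                state = next_item(tree4, state, affirmative=bool(r))
            recomputed = eap_estimate(list(responses), [by_id[i] for i in path_items])
            assert state.score == recomputed.theta
            assert state.se == recomputed.se

    def test_leaf_scores_match_dense_oracle_with_wide_grid(self, bank8):
        from catform import QuadratureGrid

        tree = build_tree(bank8, 4, QuadratureGrid.standard_normal(101, 5.0))
        by_id = {p.item_id: p for p in bank8}
        for responses in itertools.product([0, 1], repeat=4):
            state = start_traversal(tree)
            path_items = []
            for r in responses:
                path_items.append(state.current_item)
                state = next_item(tree, state, affirmative=bool(r))
            theta, se = eap_oracle(list(responses), [by_id[i] for i in path_items])
            assert state.score == pytest.approx(theta, abs=1e-3)
            assert state.se == pytest.approx(se, abs=1e-2)

    def test_paths_present_distinct_items(self, tree4, bank8):
        def walk(node, seen):
            if node.item_id is not None:
                assert node.item_id not in seen
                seen = seen | {node.item_id}
            for child in (node.left, node.right):
                if child is not None:
                    walk(child, seen)

        walk(tree4.root, set())

    def test_uncertainty_shrinks_with_depth(self, bank8):
        """Information accumulates: the average stored se at each depth is
        strictly smaller than at the depth above.  (Individual steps can widen
        the posterior slightly when a response contradicts the path so far —
        a real property of EAP posterior SD — so the trend is asserted over
        each level, not per step.)"""
        tree = build_tree(bank8, 6)
        levels: dict[int, list[float]] = {}

        def walk(node, depth):
            if node.se is not None:
                levels.setdefault(depth, []).append(node.se)
            for child in (node.left, node.right):
                if child is not None:
                    walk(child, depth + 1)

        walk(tree.root, 0)
        means = [np.mean(levels[d]) for d in sorted(levels)]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_depth_limits(self, bank8):
        with pytest.raises(IntractableError):
            build_tree(bank8 * 3, 21)
        with pytest.raises(ValueError):
            build_tree(bank8, 9)  # longer than the bank
        with pytest.raises(ValueError):
            build_tree(bank8, 0)


class TestTraversal:
    def test_affirmative_goes_right(self, tree4):
        state = start_traversal(tree4)
        right = next_item(tree4, state, affirmative=True)
        assert right.node is tree4.root.right
        assert right.depth == 1

    def test_all_negative_reaches_leftmost_leaf(self, tree4):
        state = start_traversal(tree4)
        node = tree4.root
        while not state.finished:
            state = next_item(tree4, state, affirmative=False)
            node = node.left
        assert state.node is node
        assert state.score == node.score

    def test_advancing_past_a_leaf_is_an_error(self, tree4):
        state = start_traversal(tree4)
        for _ in range(4):
            state = next_item(tree4, state, affirmative=True)
        assert state.finished
        with pytest.raises(SessionStateError):
            next_item(tree4, state, affirmative=True)


class TestOracleEquivalence:
    def test_tree_reproduces_online_cat_on_all_sequences(self, tree4, bank8):
        """The pre-computed tree must be an exact cache of the direct
        administration: same item sequence, same final score and se."""
        for responses in itertools.product([0, 1], repeat=4):
            expected_items, expected_theta, expected_se = online_cat_oracle(bank8, responses)
            state = start_traversal(tree4)
            items = []
            for r in responses:
                items.append(state.current_item)
                state = next_item(tree4, state, affirmative=bool(r))
            assert items == expected_items
            assert state.score == pytest.approx(expected_theta, abs=1e-9)
            assert state.se == pytest.approx(expected_se, abs=1e-9)

    def test_random_sequences_at_depth_seven(self, bank8):
        tree = build_tree(bank8, 7)
        rng = np.random.default_rng(77)
        for _ in range(25):
            responses = rng.integers(0, 2, size=7).tolist()
            expected_items, expected_theta, _ = online_cat_oracle(bank8, responses)
            state = start_traversal(tree)
            items = []
            for r in responses:
                items.append(state.current_item)
                state = next_item(tree, state, affirmative=bool(r))
            assert items == expected_items
            assert state.score == pytest.approx(expected_theta, abs=1e-9)


class TestTreeFiles:
    def test_record_count_matches_depth(self, tree4, tmp_path):
        path = tmp_path / "tree.tsv"
        serialize_tree(tree4, path)
        records = [l for l in path.read_text().splitlines()[1:] if l]
        assert len(records) == 2**5 - 1

    def test_round_trip_node_by_node(self, tree4, tmp_path, bank8):
        path = tmp_path / "tree.tsv"
        serialize_tree(tree4, path)
        loaded = deserialize_tree(path)
        assert loaded.depth == tree4.depth
        assert validate_tree(loaded, bank8) == []

        def pairwise(a, b):
            assert a.item_id == b.item_id
            assert (a.score is None) == (b.score is None)
            if a.score is not None:
                assert a.score == pytest.approx(b.score, abs=1e-6)
                assert a.se == pytest.approx(b.se, abs=1e-6)
            for ca, cb in ((a.left, b.left), (a.right, b.right)):
                assert (ca is None) == (cb is None)
                if ca is not None:
                    pairwise(ca, cb)

        pairwise(tree4.root, loaded.root)

    def test_truncated_file_is_a_record_count_error(self, tree4, tmp_path):
        path = tmp_path / "tree.tsv"
        serialize_tree(tree4, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(TreeFileError, match="record"):
            deserialize_tree(path)

    def test_non_finite_score_rejected(self, tree4, tmp_path):
        path = tmp_path / "tree.tsv"
        serialize_tree(tree4, path)
        text = path.read_text().replace("\t" + f"{tree4.root.left.score:.6f}" + "\t", "\tnan\t", 1)
        path.write_text(text)
        with pytest.raises(TreeFileError, match="non-finite"):
            deserialize_tree(path)


class TestValidateTree:
    def test_seeded_defects_are_detected(self, bank8):
        tree = build_tree(bank8, 3)
        tree.root.left.item_id = tree.root.item_id  # repeat on path
        codes = {v.code for v in validate_tree(tree, bank8)}
        assert DUPLICATE_ITEM_ON_PATH in codes

        tree = build_tree(bank8, 3)
        tree.root.right.item_id = "ghost"
        codes = {v.code for v in validate_tree(tree, bank8)}
        assert UNKNOWN_ITEM in codes
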