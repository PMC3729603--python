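"""Pre-computed fixed-length adaptive testing (CAT) trees.

Instead of re-estimating the trait and re-selecting items after every
response — which is costly on low-powered devices — the full space of
fixed-length adaptive administrations is pre-computed into a complete binary
tree of depth n with 2^(n+1) − 1 nodes.  The root holds the first item, which
every respondent answers.  A negative response moves to the left child, an
affirmative response to the right.  Every node except the root also stores
the EAP trait score and standard error implied by the responses along its
path; leaf nodes hold the final score for that administration.  Retrieving
the next item is then a single pointer move (amortized O(1) when the position
is stored between items).

Item selection is maximum Fisher information at the current EAP θ̂ among
items not yet used on the path, ties broken by lexicographic item id — the
canonical fixed-length CAT rule.  The tree grows as O(2^n), so depth is
capped at 20 items; in practice accuracy plateaus around 10–12 items, making
trees of that depth both tractable and sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import IntractableError, SessionStateError, TreeFileError, Violation
from .irt import (
    AbilityEstimate,
    ItemParameters,
    QuadratureGrid,
    eap_estimate,
    item_information,
)

HARD_DEPTH_CAP = 20

NODE_COUNT = "NODE_COUNT"
DUPLICATE_ITEM_ON_PATH = "DUPLICATE_ITEM_ON_PATH"
UNKNOWN_ITEM = "UNKNOWN_ITEM"
BAD_SE = "BAD_SE"
ROOT_HAS_SCORE = "ROOT_HAS_SCORE"
MISSING_SCORE = "MISSING_SCORE"

TERMINAL = "*"  # item marker for leaf records in tree files


@dataclass
class CatNode:
    """One tree node.

    Internal nodes carry the item presented there; leaves carry only the
    final score.  All nodes except the root carry the score/se attained from
    the preceding responses.
    """

    item_id: str | None = None
    score: float | None = None
    se: float | None = None
    left: "CatNode | None" = None
    right: "CatNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None


@dataclass
class CatTree:
    """A complete pre-computed adaptive-testing tree of depth ``depth``."""

    root: CatNode
    depth: int
    bank_ref: str = ""
    builder_config: dict = field(default_factory=dict)


@dataclass
class TraversalState:
    """Cursor for administering a pre-computed tree: current node plus the
    responses taken so far.  Stored between items so each step is O(1)."""

    node: CatNode
    depth: int = 0
    responses: list[int] = field(default_factory=list)

    @property
    def finished(self) -> bool:
        return self.node.is_leaf

    @property
    def current_item(self) -> str | None:
        return self.node.item_id

    @property
    def score(self) -> float | None:
        return self.node.score

    @property
    def se(self) -> float | None:
        return self.node.se


def select_item(
    theta: float,
    bank: Sequence[ItemParameters],
    used: set[str],
) -> ItemParameters:
    """Maximum-information unused item at θ; lexicographic id tie-break."""
    best: ItemParameters | None = None
    best_info = -np.inf
    for params in bank:
        if params.item_id in used:
            continue
        info = float(item_information(theta, params))
        if info > best_info or (info == best_info and best is not None and params.item_id < best.item_id):
            best, best_info = params, info
        elif best is None:
            best, best_info = params, info
    if best is None:
        raise ValueError("no unused items left in the bank")
    return best


def build_tree(
    bank: Sequence[ItemParameters],
    n: int,
    grid: QuadratureGrid | None = None,
) -> CatTree:
    """Pre-compute the complete depth-n adaptive tree for a dichotomous bank.

    The root presents the maximum-information item at the prior mean; at every
    subsequent node the presented item maximizes information at the EAP θ̂
    given the path's responses, and the node stores that score and standard
    error.  Depth-n leaves store the final score.  Deterministic.
    """
    if grid is None:
        grid = QuadratureGrid.standard_normal()
    if n > HARD_DEPTH_CAP:
        raise IntractableError(
            f"tree depth {n} exceeds the cap of {HARD_DEPTH_CAP} items "
            f"(2^{n + 1} - 1 nodes is intractable to pre-compute and store)"
        )
    if n < 1:
        raise ValueError("test length must be at least 1")
    if n > len(bank):
        raise ValueError(f"test length {n} exceeds bank size {len(bank)}")
    for params in bank:
        if not params.is_dichotomous:
            raise ValueError(f"item {params.item_id!r} is not dichotomous")
    by_id = {p.item_id: p for p in bank}
    if len(by_id) != len(bank):
        raise ValueError("bank item ids must be unique")

    prior = eap_estimate([], [], grid)

    def grow(depth: int, path_items: list[str], path_responses: list[int]) -> CatNode:
        if depth == 0:
            estimate = prior
        else:
            estimate = eap_estimate(path_responses, [by_id[i] for i in path_items], grid)
        node = CatNode()
        if depth > 0:
            node.score, node.se = estimate.theta, estimate.se
        if depth < n:
            chosen = select_item(estimate.theta, bank, set(path_items))
            node.item_id = chosen.item_id
            node.left = grow(depth + 1, path_items + [chosen.item_id], path_responses + [0])
            node.right = grow(depth + 1, path_items + [chosen.item_id], path_responses + [1])
        return node

    root = grow(0, [], [])
    return CatTree(
        root=root,
        depth=n,
        bank_ref=",".join(sorted(by_id)),
        builder_config={
            "grid_points": len(grid.points),
            "grid_bound": float(grid.points[-1]),
            "prior_mean": prior.theta,
            "prior_sd": prior.se,
        },
    )


def start_traversal(tree: CatTree) -> TraversalState:
    return TraversalState(node=tree.root)


def next_item(tree: CatTree, state: TraversalState, affirmative: bool) -> TraversalState:
    """Advance one response: left child on negative, right on affirmative.

    Returns a new state exposing the next item (or, at a leaf, the final
    stored score and se).  Constant time — no re-traversal from the root.
    """
    if state.finished:
        raise SessionStateError("test complete: cannot advance past a leaf")
    child = state.node.right if affirmative else state.node.left
    assert child is not None  # internal nodes of a complete tree have both children
    return TraversalState(
        node=child,
        depth=state.depth + 1,
        responses=state.responses + [1 if affirmative else 0],
    )


def _walk(node: CatNode):
    yield node
    if node.left is not None:
        yield from _walk(node.left)
    if node.right is not None:
        yield from _walk(node.right)


def count_nodes(tree: CatTree) -> int:
    return sum(1 for _ in _walk(tree.root))


def validate_tree(tree: CatTree, bank: Sequence[ItemParameters]) -> list[Violation]:
    """Structural checks for (possibly hand-edited) trees; violations as data."""
    out: list[Violation] = []
    expected = 2 ** (tree.depth + 1) - 1
    actual = count_nodes(tree)
    if actual != expected:
        out.append(
            Violation(NODE_COUNT, "root", f"depth {tree.depth} needs {expected} nodes, found {actual}")
        )
    if tree.root.score is not None or tree.root.se is not None:
        out.append(Violation(ROOT_HAS_SCORE, "root", "the root must not carry a score or se"))
    bank_ids = {p.item_id for p in bank}

    def check(node: CatNode, path: str, seen: set[str], depth: int) -> None:
        if depth > 0:
            if node.score is None or node.se is None:
                out.append(Violation(MISSING_SCORE, path, "non-root node lacks score/se"))
            elif node.se <= 0:
                out.append(Violation(BAD_SE, path, f"se must be positive, got {node.se}"))
        if node.item_id is not None:
            if node.item_id in seen:
                out.append(
                    Violation(DUPLICATE_ITEM_ON_PATH, path, f"item {node.item_id!r} repeated on path")
                )
            if node.item_id not in bank_ids:
                out.append(Violation(UNKNOWN_ITEM, path, f"item {node.item_id!r} not in the bank"))
            seen = seen | {node.item_id}
        if node.left is not None:
            check(node.left, path + "L", seen, depth + 1)
        if node.right is not None:
            check(node.right, path + "R", seen, depth + 1)

    check(tree.root, "root", set(), 0)
    return out


# ---------------------------------------------------------------------------
# Tree files: level-order array encoding, node i children at 2i+1 / 2i+2.
# Tab-separated columns: index, item_id (or "*" at leaves), score, se;
# header line "#depth=<n>\tbank_ref=<ref>".  Root score/se are empty.
# ---------------------------------------------------------------------------


def serialize_tree(tree: CatTree, path: str | Path) -> None:
    total = 2 ** (tree.depth + 1) - 1
    array: list[CatNode | None] = [None] * total
    def place(node: CatNode, index: int) -> None:
        array[index] = node
        if node.left is not None:
            place(node.left, 2 * index + 1)
        if node.right is not None:
            place(node.right, 2 * index + 2)
    place(tree.root, 0)
    if any(node is None for node in array):
        raise TreeFileError("tree is not complete; cannot serialize level-order")
    lines = [f"#depth={tree.depth}\tbank_ref={tree.bank_ref}"]
    for index, node in enumerate(array):
        assert node is not None
        score = "" if node.score is None else f"{node.score:.6f}"
        se = "" if node.se is None else f"{node.se:.6f}"
        lines.append(f"{index}\t{node.item_id or TERMINAL}\t{score}\t{se}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def deserialize_tree(path: str | Path) -> CatTree:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#depth="):
        raise TreeFileError("missing '#depth=' header line")
    header = dict(part.split("=", 1) for part in lines[0][1:].split("\t"))
    try:
        depth = int(header["depth"])
    except (KeyError, ValueError) as exc:
        raise TreeFileError(f"bad header: {lines[0]!r}") from exc
    expected = 2 ** (depth + 1) - 1
    records = [line for line in lines[1:] if line]
    if len(records) != expected:
        raise TreeFileError(
            f"declared depth {depth} requires {expected} records, found {len(records)}"
        )
    nodes: list[CatNode] = []
    for lineno, line in enumerate(records, start=2):
        fields = line.split("\t")
        if len(fields) != 4:
            raise TreeFileError(f"line {lineno}: expected 4 columns, got {len(fields)}")
        _, item_id, score_text, se_text = fields
        score = float(score_text) if score_text else None
        se = float(se_text) if se_text else None
        for label, value in (("score", score), ("se", se)):
            if value is not None and not np.isfinite(value):
                raise TreeFileError(f"line {lineno}: non-finite {label}")
        nodes.append(CatNode(item_id=None if item_id == TERMINAL else item_id, score=score, se=se))
    for index, node in enumerate(nodes):
        left, right = 2 * index + 1, 2 * index + 2
        if left < expected:
            node.left = nodes[left]
        if right < expected:
            node.right = nodes[right]
    return CatTree(root=nodes[0], depth=depth, bank_ref=header.get("bank_ref", ""))


# ---------------------------------------------------------------------------
# Online (non-pre-computed) CAT — the reference administration the tree caches.
# ---------------------------------------------------------------------------


def online_cat(
    bank: Sequence[ItemParameters],
    responses: Sequence[int],
    grid: QuadratureGrid | None = None,
) -> tuple[list[str], AbilityEstimate]:
    """Administer a fixed-length CAT the direct way: fresh EAP and a fresh
    maximum-information selection after every response.

    ``responses[k]`` answers the k-th presented item (0 negative,
    1 affirmative).  Returns the presented item ids and the final estimate.
    A pre-computed tree of depth ``len(responses)`` reproduces this exactly.
    """
    if grid is None:
        grid = QuadratureGrid.standard_normal()
    by_id = {p.item_id: p for p in bank}
    theta = eap_estimate([], [], grid).theta
    presented: list[str] = []
    taken: list[int] = []
    estimate = eap_estimate([], [], grid)
    for response in responses:
        chosen = select_item(theta, bank, set(presented))
        presented.append(chosen.item_id)
        taken.append(int(response))
        estimate = eap_estimate(taken, [by_id[i] for i in presented], grid)
        theta = estimate.theta
    return presented, estimate
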