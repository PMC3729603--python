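"""Pre-compute a fixed-length adaptive-testing tree and traverse it.

A depth-n tree has 2^(n+1)-1 nodes: the root asks the most informative item
at the prior mean; a "no" answer descends left, a "yes" right; every non-root
node stores the trait score and standard error implied by the path so far,
and leaves hold the final score.  Administration is pointer-chasing only.
"""

from catform import (
    FixtureConfig,
    build_tree,
    count_nodes,
    generate_item_bank,
    next_item,
    online_cat,
    start_traversal,
)

bank = generate_item_bank(FixtureConfig(seed=8, items=8, responses=2))
tree = build_tree(bank, n=4)
print(f"depth-4 tree: {count_nodes(tree)} nodes (= 2^5 - 1)")
print("first item (max information at theta=0):", tree.root.item_id)

answers = [True, False, True, True]  # yes, no, yes, yes
state = start_traversal(tree)
for answer in answers:
    print(f"  item {state.current_item}: {'yes' if answer else 'no'}", end="")
    state = next_item(tree, state, affirmative=answer)
    print(f" -> theta = {state.score:+.4f}, se = {state.se:.4f}")
print(f"final score after 4 items: {state.score:+.4f} (se {state.se:.4f})")

items, estimate = online_cat(bank, [int(a) for a in answers])
print("online CAT (fresh EAP + selection each step) gives:",
      f"{estimate.theta:+.4f} via items {items}")
# The pre-computed traversal and the online run agree exactly: the tree is a
# complete cache of every possible fixed-length adaptive administration.
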