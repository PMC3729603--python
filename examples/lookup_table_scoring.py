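"""Pre-compute an exhaustive lookup table of IRT scores and use it.

For a 3-item yes/no instrument there are 2^3 = 8 possible response patterns;
each table entry stores the EAP latent-trait estimate for one pattern, so
scoring at administration time is a single exact-match retrieval.
"""

from catform import (
    FixtureConfig,
    ResponsePattern,
    build_instrument,
    build_lookup_table,
    eap_estimate,
    generate_item_bank,
    score_lookup,
)

config = FixtureConfig(seed=3, items=3, responses=2, with_instructions=False)
instrument = build_instrument(config)
bank = generate_item_bank(config)

table = build_lookup_table(instrument, bank)
print(f"table has {len(table)} entries (= 2^{len(instrument.items)})")
for key in sorted(table.entries):
    print(f"  pattern {key} -> theta = {table.entries[key]:+.4f}")

pattern = ResponsePattern(values=(1.0, 0.0, 1.0))
score = score_lookup(table, pattern)
direct = eap_estimate([1, 0, 1], bank).theta
print(f"lookup score for (yes, no, yes): {score:+.4f}")
print(f"direct EAP for the same pattern: {direct:+.4f}")
# The table is a cache of the EAP computation: all-affirmative patterns score
# highest, all-negative lowest, and lookup agrees with direct estimation.
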