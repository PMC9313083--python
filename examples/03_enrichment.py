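"""Over-representation analysis of a winner gene list against gene sets.

The query hits one 8-gene set almost completely; the hypergeometric upper
tail with Benjamini–Hochberg correction ranks it far above two decoy sets.
"""

from degnet import GeneSetCollection, ora

universe = frozenset(f"g{i}" for i in range(60))
collection = GeneSetCollection(
    {
        "cell_cycle": frozenset(f"g{i}" for i in range(8)),
        "adhesion": frozenset(f"g{i}" for i in range(20, 30)),
        "metabolism": frozenset(f"g{i}" for i in range(40, 52)),
    },
    universe,
)

query = {f"g{i}" for i in range(7)} | {"g25", "g45"}  # 7/8 of cell_cycle
results = ora(query, collection, fdr_max=0.05)
print(results.to_string(index=False))
# p_value is P(overlap >= k) under random draws from the universe; fdr is the
# BH-corrected value over the three tested sets. Only cell_cycle is called.
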