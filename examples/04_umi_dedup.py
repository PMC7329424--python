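"""Directional UMI deduplication within one (cell, gene) group.

UMI A absorbs UMI B when they differ at exactly one position and
count(A) >= 2*count(B) - 1: an error-derived UMI should be much rarer
than the molecule it came from. Equal-count neighbours stay separate —
there is no evidence either derives from the other.
"""

from dropsketch.dedup import count_molecules, directional_edges

groups = {
    "error chain":      {"AAAAAAAAAA": 10, "AAAAAAAAAT": 4, "TAAAAAAAAT": 2},
    "balanced pair":    {"AAAAAAAAAA": 5, "AAAAAAAAAT": 5},
    "distant UMIs":     {"AAAAAAAAAA": 3, "GGGGGGGGGG": 3},
}

for name, counts in groups.items():
    n, reps = count_molecules(counts, factor=2)
    edges = {a: b for a, b in directional_edges(counts, 2).items() if b}
    print(f"{name}: {counts}")
    print(f"  edges {edges or '{}'} -> {n} molecule(s), representatives {reps}")
# 21 raw reads across the three groups collapse to 5 molecules: the
# error chain is one over-amplified molecule, the other groups are two
# genuine molecules each.
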