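"""Cell-barcode whitelisting by the sorted prefix-sum rule, plus rescue.

Barcode counts are sorted descending; a barcode is admitted while its
inclusive prefix sum stays below fraction x total reads. Barcodes that
miss the list are rescued at mapping time when they sit within edit
distance one of exactly one whitelisted barcode.
"""

from collections import Counter

from dropsketch.barcodes import BarcodeCounts, build_whitelist, correct_barcode

# a toy count table: two real cells and an error tail
counts = BarcodeCounts(
    counts=Counter({
        "AAAAAAAAAAAAAAAA": 50,
        "CCCCCCCCCCCCCCCC": 30,
        "AAAAAAAATAAAAAAA": 15,  # 1-substitution shadow of the first cell
        "GGGGGGGGGGGGGGGG": 5,
    }),
    total=100,
)

wl = build_whitelist(counts, fraction=0.9)
print(f"whitelist at fraction 0.9: {sorted(wl.members)}")
# prefix sums 50, 80, 95, 100: the first two stay below 90 and are kept

for cb in ("AAAAAAAATAAAAAAA", "CCCCCCCCCCCCCGCC", "TTTTTTTTTTTTTTTT"):
    print(f"correct {cb} -> {correct_barcode(cb, wl)}")
# the first two are one substitution from a unique member and get
# rescued; the last is far from everything and its read would be dropped
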