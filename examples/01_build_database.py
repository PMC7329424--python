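"""Build a minhash feature database over a tiny two-gene transcriptome.

Each transcript is cut into 56-base windows every 41 bases; each window
is represented by the 16 smallest hashes of its canonical 16-mers. The
database maps each such feature to the (transcript, window) locations
where it occurs.
"""

import numpy as np

from dropsketch import Params, SequenceRecord, Taxonomy, build_database, window_spans

rng = np.random.default_rng(0)
seq = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

tax = Taxonomy()
records = []
for tx, gene, length in [("tx1", "geneA", 200), ("tx2", "geneA", 150), ("tx3", "geneB", 120)]:
    tax.add(tx, gene)
    records.append(SequenceRecord(tx, seq(length)))

params = Params.for_read_length(98)  # k=16, s=16 -> w=56, t=41, r=3
db = build_database(records, tax, params)

print(f"window geometry for R=98: w={params.w}, t={params.t}, r={params.r}")
for rec, n_win in zip(records, db.transcript_window_counts):
    spans = window_spans(len(rec.sequence), params)
    print(f"  {rec.id}: {len(rec.sequence)} bp -> {n_win} windows "
          f"{[(s.start, s.end) for s in spans]}")
print(f"feature table: {len(db.table)} distinct features")
multi = sum(1 for locs in db.table.values() if len(locs) > 1)
print(f"  {multi} features occur at more than one (transcript, window) location")
# Each full 56-base window contributes at most s=16 features, so the
# table size tracks (number of windows) x 16 minus shared features.
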