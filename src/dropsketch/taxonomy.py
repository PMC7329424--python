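"""Two-level transcript → gene taxonomy.

Multi-transcript hits are resolved to genes through this mapping; the
stable gene order recorded here also fixes the column order of the
output matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class TaxonomyError(ValueError):
    """Inconsistent transcript→gene annotation."""


@dataclass
class Taxonomy:
    """Transcript→gene map plus stable orderings.

    ``gene_order`` is the order of first appearance (e.g. in the GTF);
    ``transcript_order`` likewise. Every transcript maps to exactly one
    gene.
    """

    tx2gene: dict[str, str] = field(default_factory=dict)
    gene_order: list[str] = field(default_factory=list)
    transcript_order: list[str] = field(default_factory=list)

    def add(self, transcript_id: str, gene_id: str) -> None:
        prev = self.tx2gene.get(transcript_id)
        if prev is not None:
            if prev != gene_id:
                raise TaxonomyError(
                    f"transcript {transcript_id!r} annotated to two genes: "
                    f"{prev!r} and {gene_id!r}"
                )
            return
        self.tx2gene[transcript_id] = gene_id
        self.transcript_order.append(transcript_id)
        if gene_id not in self._gene_set:
            self._gene_set.add(gene_id)
            self.gene_order.append(gene_id)

    def __post_init__(self) -> None:
        self._gene_set = set(self.gene_order)

    def gene_of(self, transcript_id: str) -> str:
        return self.tx2gene[transcript_id]

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)

    @property
    def n_transcripts(self) -> int:
        return len(self.tx2gene)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_order)}

    def to_dict(self) -> dict:
        return {
            "tx2gene": dict(self.tx2gene),
            "gene_order": list(self.gene_order),
            "transcript_order": list(self.transcript_order),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Taxonomy":
        return cls(
            tx2gene=dict(d["tx2gene"]),
            gene_order=list(d["gene_order"]),
            transcript_order=list(d["transcript_order"]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxonomy):
            return NotImplemented
        return (
            self.tx2gene == other.tx2gene
            and self.gene_order == other.gene_order
            and self.transcript_order == other.transcript_order
        )
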