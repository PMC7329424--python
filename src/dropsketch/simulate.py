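"""Synthetic droplet scRNA-seq data with known ground truth.

Generates a toy transcriptome (multi-isoform genes sharing sequence,
optional gene pairs sharing a verbatim block to provoke cross-gene
ambiguity), a GTF annotation, and Chromium-v2-style paired FASTQ reads:
mate 1 = 16 nt cell barcode + 10 nt UMI, mate 2 = R bases of cDNA,
antisense with probability 1/2. PCR duplication and independent
substitution-error rates for CB, UMI and cDNA are simulated per base.

Conventions chosen for exact end-to-end accounting (see docs/methods.md):
molecule start positions lie on the stride grid by default, UMIs within
one (cell, gene) group are distinct with pairwise Hamming distance >= 2,
and the true cell barcodes are pairwise distance >= 3 apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import SequenceRecord, write_fasta, write_fastq
from .matrix_output import CountMatrix, assemble_matrix, write_matrix
from .dedup import MoleculeCount
from .params import Params, default_stride, default_window_size
from .taxonomy import Taxonomy

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator; the defaults are the baseline
    error-free experiment (errors and duplication are opt-in)."""

    n_genes: int = 20
    isoforms_per_gene: int = 2
    shared_block_genes: int = 0  # number of gene PAIRS sharing a verbatim block
    transcript_length: tuple[int, int] = (400, 800)
    isoform_shared_fraction: float = 0.6
    n_cells: int = 50
    cb_len: int = 16
    min_cb_distance: int = 3
    umi_len: int = 10
    mean_molecules: float = 20.0  # Poisson mean per (cell, gene)
    pcr_rate: float = 0.0  # extra copies ~ Binomial(4, pcr_rate)
    cb_error_rate: float = 0.0  # per-base substitution probabilities
    umi_error_rate: float = 0.0
    cdna_error_rate: float = 0.0
    read_length: int = 98
    window_aligned: bool = True  # molecule starts on the stride grid
    stride: int | None = None  # grid for window_aligned; default (w-k+1) for k=16

    def __post_init__(self) -> None:
        for name in ("pcr_rate", "cb_error_rate", "umi_error_rate", "cdna_error_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.transcript_length[0] < self.read_length:
            raise ValueError("transcripts must be at least one read long")
        if 2 * self.shared_block_genes > self.n_genes:
            raise ValueError("not enough genes for the requested shared-block pairs")

    @property
    def grid(self) -> int:
        if self.stride is not None:
            return self.stride
        k = 16
        return default_stride(default_window_size(self.read_length, k), k)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        if "transcript_length" in d:
            d["transcript_length"] = tuple(d["transcript_length"])
        return cls(**d)


@dataclass(frozen=True)
class ReadProvenance:
    """Where one synthetic read came from, error positions included."""

    name: str
    molecule_id: int
    cell: str  # true CB
    gene: str
    transcript: str
    position: int  # 0-based start on the transcript
    umi: str  # true UMI
    revcomp: bool
    cb_errors: tuple[int, ...]
    umi_errors: tuple[int, ...]
    cdna_errors: tuple[int, ...]


@dataclass
class SimTruth:
    """Ground truth: the molecule matrix plus per-read provenance."""

    matrix: CountMatrix
    provenance: list[ReadProvenance]
    barcodes: list[str]  # the true CB set

    def molecules_by_pair(self) -> dict[tuple[str, str], int]:
        return self.matrix.to_dict()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, tuple[int, ...]]:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq, ()
    chars = list(seq)
    positions = []
    for i, c in enumerate(chars):
        if rng.random() < rate:
            alternatives = [b for b in "ACGT" if b != c]
            chars[i] = alternatives[rng.integers(0, 3)]
            positions.append(i)
    return "".join(chars), tuple(positions)


def _distinct_codes(
    rng: np.random.Generator, n: int, length: int, min_distance: int
) -> list[str]:
    """Random nucleotide codes with pairwise Hamming >= min_distance."""
    codes: list[str] = []
    while len(codes) < n:
        cand = _random_seq(rng, length)
        if all(
            sum(a != b for a, b in zip(cand, c)) >= min_distance for c in codes
        ):
            codes.append(cand)
    return codes


def simulate_reference(
    config: SimConfig, seed: int
) -> tuple[list[SequenceRecord], Taxonomy]:
    """Build the toy transcriptome and its taxonomy.

    Isoforms of one gene share a prefix of ``isoform_shared_fraction``
    of the gene length; the first ``shared_block_genes`` pairs of genes
    additionally embed one verbatim block (>= read length, placed on
    the stride grid) in their first isoforms.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.transcript_length
    grid = config.grid
    block_len = max(config.read_length, 150)
    records: list[SequenceRecord] = []
    tax = Taxonomy()
    shared_blocks = [
        _random_seq(rng, block_len) for _ in range(config.shared_block_genes)
    ]
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:04d}"
        L = int(rng.integers(lo, hi + 1))
        base = _random_seq(rng, L)
        if g // 2 < config.shared_block_genes and config.shared_block_genes:
            pair = g // 2
            if pair < config.shared_block_genes:
                # splice the pair's block in at one stride step from the start
                block = shared_blocks[pair]
                base = base[:grid] + block + base[grid + block_len :]
                if len(base) < L:
                    base = base + _random_seq(rng, L - len(base))
        keep = int(config.isoform_shared_fraction * L)
        for i in range(config.isoforms_per_gene):
            tx_id = f"{gene_id}.T{i + 1}"
            if i == 0:
                seq = base
            else:
                seq = base[:keep] + _random_seq(rng, L - keep)
            records.append(SequenceRecord(id=tx_id, sequence=seq))
            tax.add(tx_id, gene_id)
    return records, tax


def _aligned_starts(length: int, read_length: int, grid: int) -> list[int]:
    return list(range(0, length - read_length + 1, grid))


def simulate_experiment(
    reference: tuple[list[SequenceRecord], Taxonomy],
    config: SimConfig,
    seed: int,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], SimTruth]:
    """Draw molecules and reads; return R1 records, R2 records and truth.

    Each molecule is (cell, gene → random isoform, fresh UMI, random
    start); it yields 1 + Binomial(4, pcr_rate) reads, each with
    independent substitution errors. The truth matrix counts molecules,
    never reads.
    """
    records, tax = reference
    rng = np.random.default_rng(seed)
    by_id = {r.id: r for r in records}
    isoforms: dict[str, list[str]] = {}
    for r in records:
        isoforms.setdefault(tax.gene_of(r.id), []).append(r.id)

    barcodes = _distinct_codes(rng, config.n_cells, config.cb_len, config.min_cb_distance)
    R = config.read_length
    grid = config.grid
    r1: list[tuple[str, str, str]] = []
    r2: list[tuple[str, str, str]] = []
    provenance: list[ReadProvenance] = []
    molecule_counts: list[MoleculeCount] = []
    serial = 0
    molecule_id = 0
    for cb in barcodes:
        for gene in tax.gene_order:
            n_mol = int(rng.poisson(config.mean_molecules))
            if n_mol == 0:
                continue
            group_umis: list[str] = []
            for _ in range(n_mol):
                # fresh UMI, pairwise Hamming >= 2 within the group so that
                # distinct molecules stay distinguishable under the
                # directional collapse
                while True:
                    umi = _random_seq(rng, config.umi_len)
                    if all(
                        sum(a != b for a, b in zip(umi, u)) >= 2 for u in group_umis
                    ):
                        break
                group_umis.append(umi)
                # pick an isoform long enough for one read
                while True:
                    tx_id = isoforms[gene][rng.integers(0, len(isoforms[gene]))]
                    seq = by_id[tx_id].sequence
                    if len(seq) >= R:
                        break
                if config.window_aligned:
                    starts = _aligned_starts(len(seq), R, grid)
                    start = starts[rng.integers(0, len(starts))]
                else:
                    start = int(rng.integers(0, len(seq) - R + 1))
                n_reads = 1 + int(rng.binomial(4, config.pcr_rate))
                for _copy in range(n_reads):
                    cb_obs, cb_err = _mutate(rng, cb, config.cb_error_rate)
                    umi_obs, umi_err = _mutate(rng, umi, config.umi_error_rate)
                    cdna = seq[start : start + R]
                    cdna_obs, cdna_err = _mutate(rng, cdna, config.cdna_error_rate)
                    rc = bool(rng.random() < 0.5)
                    if rc:
                        cdna_obs = reverse_complement(cdna_obs)
                    name = f"r{serial:07d}"
                    serial += 1
                    r1.append((name, cb_obs + umi_obs, "I" * (config.cb_len + config.umi_len)))
                    r2.append((name, cdna_obs, "I" * R))
                    provenance.append(
                        ReadProvenance(
                            name=name,
                            molecule_id=molecule_id,
                            cell=cb,
                            gene=gene,
                            transcript=tx_id,
                            position=start,
                            umi=umi,
                            revcomp=rc,
                            cb_errors=cb_err,
                            umi_errors=umi_err,
                            cdna_errors=cdna_err,
                        )
                    )
                molecule_id += 1
            molecule_counts.append(MoleculeCount(cell=cb, gene=gene, molecules=n_mol))
    truth = SimTruth(
        matrix=assemble_matrix(molecule_counts, tax),
        provenance=provenance,
        barcodes=barcodes,
    )
    return r1, r2, truth


def simulate_to_dir(
    config: SimConfig, outdir: str | Path, seed: int
) -> dict[str, Path]:
    """Write ref.fa, ann.gtf, R1/R2 FASTQ (gzipped) and the truth matrix.

    Byte-identical for identical (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, tax = simulate_reference(config, seed)
    fasta = outdir / "ref.fa"
    write_fasta(records, fasta)
    gtf = outdir / "ann.gtf"
    write_gtf(records, tax, gtf)
    # reads get their own stream so reference tweaks don't shift read draws
    r1, r2, truth = simulate_experiment((records, tax), config, seed + 1)
    p1 = outdir / "R1.fastq.gz"
    p2 = outdir / "R2.fastq.gz"
    write_fastq(r1, p1)
    write_fastq(r2, p2)
    truth_dir = outdir / "truth"
    write_matrix(truth.matrix, truth_dir, dialect="matrixmarket")
    with open(outdir / "barcodes.true.tsv", "wt") as fh:
        for cb in sorted(truth.barcodes):
            fh.write(cb + "\n")
    return {
        "fasta": fasta,
        "gtf": gtf,
        "r1": p1,
        "r2": p2,
        "truth": truth_dir,
        "true_barcodes": outdir / "barcodes.true.tsv",
    }


def write_gtf(
    records: Sequence[SequenceRecord], taxonomy: Taxonomy, path: str | Path
) -> None:
    """Minimal transcriptome GTF: one transcript + one exon row each."""
    with open(path, "wt") as fh:
        fh.write("# synthetic annotation\n")
        for rec in records:
            gene = taxonomy.gene_of(rec.id)
            attrs = f'gene_id "{gene}"; transcript_id "{rec.id}";'
            for feature in ("transcript", "exon"):
                fh.write(
                    f"{rec.id}\tsim\t{feature}\t1\t{len(rec.sequence)}\t.\t+\t.\t{attrs}\n"
                )
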