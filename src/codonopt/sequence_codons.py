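"""Coding-sequence handling and codon / amino-acid composition matrices.

A coding sequence (CDS) is read as non-overlapping triplets in frame from the
first position.  The 61 sense codons of the standard genetic code form the
fixed column space of every composition matrix; stop codons (TAA, TAG, TGA)
are excluded from counting by default because the stabilization statistics
downstream are defined over coding codons only.

Per-gene "occurrence" of a codon is stored both as a raw count and as a
frequency (count divided by the gene's total sense codons).  Frequencies are
the default input to the correlation statistics so that genes of very
different CDS length are comparable; raw counts are retained for usage
summaries and for the leave-out-most-abundant-synonymous-codon analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CODON_TO_AA",
    "AMINO_ACIDS",
    "AA_TO_CODONS",
    "CodingSequence",
    "CodonCounts",
    "CodonCompositionMatrix",
    "AminoAcidComposition",
    "ValidationReport",
    "read_cds_fasta",
    "count_codons",
    "build_composition",
    "amino_acid_composition",
    "write_composition_tsv",
    "read_composition_tsv",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)

#: The 61 sense codons in fixed alphabetical order (the column order of every
#: composition matrix and TSV written by this package).
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD_TABLE.forward_table))

#: codon -> one-letter amino acid, standard genetic code.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)

#: The 20 amino acids in alphabetical one-letter order.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

#: amino acid -> tuple of synonymous codons (alphabetical).
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AMINO_ACIDS
}

_VALID_CHARS = frozenset("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """A validated coding sequence: uppercase A/C/G/T, length divisible by 3."""

    gene_id: str
    seq: str


@dataclass
class ValidationReport:
    """Record-level validation outcome of a FASTA read."""

    n_total: int = 0
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, reason)

    @property
    def n_valid(self) -> int:
        return self.n_total - len(self.excluded)


@dataclass
class CodonCounts:
    """Per-gene occurrence of each of the 61 sense codons."""

    gene_id: str
    counts: dict[str, int]
    n_codons: int
    has_internal_stop: bool = False


@dataclass
class CodonCompositionMatrix:
    """Genes x 61 codon frequencies plus the underlying integer counts.

    ``freq`` rows sum to 1 for every gene with at least one sense codon.
    """

    genes: list[str]
    freq: pd.DataFrame
    raw: pd.DataFrame
    internal_stop: pd.Series | None = None


@dataclass
class AminoAcidComposition:
    """Genes x 20 amino-acid frequencies (synonymous codons pooled)."""

    genes: list[str]
    freq: pd.DataFrame


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_cds_fasta(path: str | Path) -> tuple[list[CodingSequence], ValidationReport]:
    """Read coding sequences from a FASTA file.

    Sequences are uppercased and U is mapped to T.  Records whose length is
    zero or not divisible by 3, or that contain characters outside A/C/G/T
    (ambiguity codes included), are excluded and listed in the report —
    a skipped triplet would silently shift every downstream frequency, so
    ambiguous records are rejected whole.  Duplicate ids raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    report = ValidationReport()
    records: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        report.n_total += 1
        gene_id = rec.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id in FASTA: {gene_id!r}")
        seen.add(gene_id)
        seq = _normalize(str(rec.seq))
        if len(seq) == 0:
            report.excluded.append((gene_id, "empty sequence"))
            continue
        bad = set(seq) - _VALID_CHARS
        if bad:
            report.excluded.append(
                (gene_id, f"non-nucleotide characters: {''.join(sorted(bad))}")
            )
            continue
        if len(seq) % 3 != 0:
            report.excluded.append((gene_id, f"length {len(seq)} not divisible by 3"))
            continue
        records.append(CodingSequence(gene_id=gene_id, seq=seq))
    if report.n_total == 0:
        raise ValueError(f"empty FASTA file: {path}")
    return records, report


def count_codons(
    cds: CodingSequence, drop_stop: bool = True, drop_start: bool = False
) -> CodonCounts:
    """Count non-overlapping in-frame triplets of a validated CDS.

    Stop triplets are excluded from the 61-codon count when ``drop_stop`` is
    on (default); the first codon is excluded when ``drop_start`` is on
    (default off).  A stop triplet before the final position is flagged in
    the output but does not truncate counting — composition is a pure
    sequence property here, independent of translatability.
    """
    seq = cds.seq
    if len(seq) % 3 != 0:
        raise ValueError(
            f"{cds.gene_id}: CDS length {len(seq)} not divisible by 3"
        )
    counts = dict.fromkeys(SENSE_CODONS, 0)
    n_triplets = len(seq) // 3
    has_internal_stop = False
    start = 1 if drop_start else 0
    for i in range(n_triplets):
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i < n_triplets - 1:
                has_internal_stop = True
            if drop_stop:
                continue
            # stop codons are outside the 61-codon key space; when they are
            # not dropped they still cannot be counted against sense keys
            continue
        if i < start:
            continue
        counts[codon] += 1
    return CodonCounts(
        gene_id=cds.gene_id,
        counts=counts,
        n_codons=sum(counts.values()),
        has_internal_stop=has_internal_stop,
    )


def build_composition(
    cds_list: Sequence[CodingSequence],
    drop_stop: bool = True,
    drop_start: bool = False,
) -> CodonCompositionMatrix:
    """Assemble the genes x 61 composition matrix, rows in input order.

    Genes with zero countable sense codons are excluded with a warning.
    """
    if len(cds_list) == 0:
        raise ValueError("empty CDS list")
    rows, genes, flags = [], [], []
    for cds in cds_list:
        cc = count_codons(cds, drop_stop=drop_stop, drop_start=drop_start)
        if cc.n_codons == 0:
            warnings.warn(
                f"{cds.gene_id}: no sense codons, excluded from composition",
                stacklevel=2,
            )
            continue
        genes.append(cds.gene_id)
        rows.append([cc.counts[c] for c in SENSE_CODONS])
        flags.append(cc.has_internal_stop)
    if not rows:
        raise ValueError("no gene with countable sense codons")
    raw = pd.DataFrame(rows, index=genes, columns=list(SENSE_CODONS), dtype=int)
    freq = raw.div(raw.sum(axis=1), axis=0)
    return CodonCompositionMatrix(
        genes=genes,
        freq=freq,
        raw=raw,
        internal_stop=pd.Series(flags, index=genes, dtype=bool),
    )


def amino_acid_composition(comp: CodonCompositionMatrix) -> AminoAcidComposition:
    """Pool synonymous-codon frequencies into amino-acid frequencies."""
    aa_freq = pd.DataFrame(
        {aa: comp.freq[list(AA_TO_CODONS[aa])].sum(axis=1) for aa in AMINO_ACIDS},
        index=comp.freq.index,
    )
    return AminoAcidComposition(genes=list(comp.genes), freq=aa_freq)


def write_composition_tsv(comp: CodonCompositionMatrix, path: str | Path) -> None:
    """Write frequencies: gene_id column then the 61 codon columns."""
    out = comp.freq.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_composition_tsv(path: str | Path) -> pd.DataFrame:
    """Read a composition TSV back into a genes x 61 frequency frame."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    missing = set(SENSE_CODONS) - set(df.columns)
    if missing:
        raise ValueError(f"composition TSV missing codon columns: {sorted(missing)}")
    return df[list(SENSE_CODONS)]
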