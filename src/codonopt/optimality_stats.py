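"""Codon and amino-acid stabilization coefficients (CSC / ASC).

The CSC of a codon is the Pearson correlation, across genes, between the
codon's per-gene occurrence (frequency by default) and mRNA stability.  The
ASC is the analogous correlation for amino-acid occurrence.  Stability is a
per-gene scalar where larger means more stable; the default convention is
the negated first-order decay constant (-rate_k), which is defined for every
gene including apparent stabilizers (k <= 0).  log2 half-life is available
as an alternative convention (genes with k <= 0 are excluded there).

Because a Pearson correlation is invariant under positive affine transforms
of either variable, the CSC does not depend on the units or offset of the
stability measure — only its orientation.

The leave-out variant of the ASC recomputes each amino acid's per-gene
occurrence after removing its single most abundant synonymous codon
(abundance = summed raw counts across genes).  Amino acids encoded by one
codon (Met, Trp) are undefined there.  This variant exposes amino acids
whose apparent optimality is driven by one dominant codon rather than a
shared amino-acid-level effect.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_codons import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    SENSE_CODONS,
    AminoAcidComposition,
    CodonCompositionMatrix,
)

__all__ = [
    "make_stability",
    "compute_csc",
    "compute_asc",
    "asc_drop_most_abundant",
    "correlate_csc_tables",
    "map_anticodon_to_codon",
    "correlate_csc_with_covariate",
    "codon_usage_correlation",
    "write_coefficient_tsv",
    "read_coefficient_tsv",
]

MIN_GENES = 10

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def make_stability(
    estimates: pd.DataFrame, convention: str = "neg_rate"
) -> pd.Series:
    """Per-gene stability from decay estimates (larger = more stable).

    ``neg_rate``: -rate_k for every gene with a finite rate.
    ``log2_halflife``: log2(ln2 / rate_k); genes with rate_k <= 0 excluded.
    """
    k = estimates["rate_k"].astype(float)
    if convention == "neg_rate":
        s = -k
    elif convention == "log2_halflife":
        s = np.log2(np.log(2.0) / k[k > 0])
    else:
        raise ValueError(f"unknown stability convention {convention!r}")
    s = s[np.isfinite(s)]
    s.name = "stability"
    return s


def _pearson_columns(
    stability: pd.Series,
    matrix: pd.DataFrame,
    raw: pd.DataFrame | None,
    na_absent_frac: float,
) -> pd.DataFrame:
    stability = stability.dropna()
    genes = matrix.index.intersection(stability.index)
    if len(genes) < MIN_GENES:
        raise ValueError(
            f"need at least {MIN_GENES} genes with stability; have {len(genes)}"
        )
    s = stability.loc[genes].to_numpy(dtype=float)
    rows = []
    for col in matrix.columns:
        x = matrix.loc[genes, col].to_numpy(dtype=float)
        ok = np.isfinite(x)  # pairwise-complete within the intersection
        absent = None
        if raw is not None and col in raw.columns:
            absent = (raw.loc[genes, col][ok] == 0).mean()
        if (
            ok.sum() < MIN_GENES
            or np.std(x[ok]) == 0
            or (absent is not None and absent > na_absent_frac)
        ):
            rows.append((col, np.nan, np.nan, int(ok.sum())))
            continue
        r, p = stats.pearsonr(x[ok], s[ok])
        rows.append((col, r, p, int(ok.sum())))
    out = pd.DataFrame(rows, columns=["key", "r", "p", "n"]).set_index("key")
    return out


def compute_csc(
    stability: pd.Series,
    comp: CodonCompositionMatrix,
    label: str | None = None,
    na_absent_frac: float = 0.99,
) -> pd.DataFrame:
    """CSC table: Pearson r (and p, n) per sense codon against stability.

    Codons with zero variance across genes, or absent from more than
    ``na_absent_frac`` of genes, are reported NA rather than as
    near-degenerate correlations.
    """
    out = _pearson_columns(stability, comp.freq[list(SENSE_CODONS)], comp.raw, na_absent_frac)
    out.index.name = "codon"
    out.attrs["label"] = label
    return out


def compute_asc(
    stability: pd.Series,
    aa: AminoAcidComposition,
    label: str | None = None,
) -> pd.DataFrame:
    """ASC table: Pearson r per amino acid (all synonymous codons pooled)."""
    out = _pearson_columns(stability, aa.freq[list(AMINO_ACIDS)], None, 1.0)
    out.index.name = "aa"
    out["variant"] = "all-codons"
    out.attrs["label"] = label
    return out


def most_abundant_synonymous(comp: CodonCompositionMatrix) -> dict[str, str]:
    """Per amino acid, the synonymous codon with the largest summed raw count
    (ties broken alphabetically)."""
    totals = comp.raw.sum(axis=0)
    # max() keeps the first (alphabetically first) codon on ties
    return {aa: max(AA_TO_CODONS[aa], key=lambda c: totals[c]) for aa in AMINO_ACIDS}


def asc_drop_most_abundant(
    stability: pd.Series,
    comp: CodonCompositionMatrix,
    label: str | None = None,
    renormalize: str = "total",
) -> pd.DataFrame:
    """ASC after removing each amino acid's most abundant synonymous codon.

    The reduced per-gene amino-acid occurrence is the summed count of the
    remaining synonymous codons divided by the gene's total sense codons
    (``renormalize='total'``, default) or by the gene's remaining-codon
    total (``'remaining'``).  Single-codon amino acids (Met, Trp) are NA.
    """
    dominant = most_abundant_synonymous(comp)
    n_codons = comp.raw.sum(axis=1)
    reduced = {}
    for aa in AMINO_ACIDS:
        rest = [c for c in AA_TO_CODONS[aa] if c != dominant[aa]]
        if not rest:
            reduced[aa] = pd.Series(np.nan, index=comp.raw.index)
            continue
        counts = comp.raw[rest].sum(axis=1)
        if renormalize == "total":
            reduced[aa] = counts / n_codons
        elif renormalize == "remaining":
            denom = n_codons - comp.raw[dominant[aa]]
            reduced[aa] = counts / denom.replace(0, np.nan)
        else:
            raise ValueError(f"unknown renormalization {renormalize!r}")
    mat = pd.DataFrame(reduced, index=comp.raw.index)[list(AMINO_ACIDS)]
    keep = [aa for aa in AMINO_ACIDS if mat[aa].notna().any()]
    out = _pearson_columns(stability, mat[keep], None, 1.0)
    out = out.reindex(list(AMINO_ACIDS))
    out["n"] = out["n"].fillna(0).astype(int)
    out.index.name = "aa"
    out["variant"] = "drop-most-abundant"
    out.attrs["label"] = label
    out.attrs["dropped"] = dominant
    return out


def correlate_csc_tables(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation between two CSC tables over shared non-NA codons."""
    joined = a[["r"]].join(b[["r"]], lsuffix="_a", rsuffix="_b").dropna()
    if len(joined) < MIN_GENES:
        raise ValueError("fewer than 10 shared non-NA codons")
    rho, p = stats.spearmanr(joined["r_a"], joined["r_b"])
    return float(rho), float(p)


def map_anticodon_to_codon(anticodon: str) -> str:
    """Watson-Crick codon of a tRNA anticodon: the reverse complement
    (RNA alphabet accepted, e.g. anticodon UUU -> codon AAA)."""
    ac = anticodon.upper().replace("U", "T")
    return ac.translate(_COMPLEMENT)[::-1]


def correlate_csc_with_covariate(
    csc: pd.DataFrame, covariate: pd.Series, key: str = "codon"
) -> tuple[float, float]:
    """Spearman correlation of CSC with a per-codon covariate (e.g. tRNA level).

    ``key='anticodon'`` maps covariate keys to their Watson-Crick codons
    first (exact pairing only; wobble decoding is not modeled).  Unmatched
    codons are dropped pairwise.
    """
    cov = covariate.copy()
    if key == "anticodon":
        cov.index = [map_anticodon_to_codon(a) for a in cov.index]
    elif key != "codon":
        raise ValueError(f"unknown covariate key {key!r}")
    cov = cov[~cov.index.duplicated()]
    joined = csc[["r"]].join(cov.rename("cov"), how="inner").dropna()
    if len(joined) < MIN_GENES:
        raise ValueError("fewer than 10 matched codons")
    rho, p = stats.spearmanr(joined["r"], joined["cov"])
    return float(rho), float(p)


def codon_usage_correlation(
    comp: CodonCompositionMatrix, csc: pd.DataFrame
) -> tuple[float, float]:
    """Spearman correlation between transcriptome-wide codon usage
    (total raw count per codon / grand total) and the CSC.

    Returns (nan, nan) when usage has zero variance.
    """
    usage = comp.raw.sum(axis=0) / comp.raw.to_numpy().sum()
    joined = csc[["r"]].join(usage.rename("usage")).dropna()
    if len(joined) < MIN_GENES:
        raise ValueError("fewer than 10 codons with defined CSC")
    if joined["usage"].std() == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(joined["usage"], joined["r"])
    return float(rho), float(p)


def write_coefficient_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a CSC/ASC table; the dataset label becomes a column."""
    out = table.copy()
    if table.attrs.get("label") is not None:
        out["dataset"] = table.attrs["label"]
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_coefficient_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
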