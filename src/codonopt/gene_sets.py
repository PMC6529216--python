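"""Optimality scoring of genes and group contrasts.

Genes are scored by their codon content weighted with the CSC: the default
score is the frequency-weighted mean CSC (renormalized over codons with a
defined CSC), and ``percent_optimal`` — the fraction of a gene's codons
whose CSC is positive — is reported alongside as the alternative ranking.
Extreme sets (top/bottom n, default 500) feed the group contrasts used
throughout: Wilcoxon rank-sum, two-sample Kolmogorov-Smirnov, or a linear
model on the set indicator (whose coefficient is the difference of group
means).

``perturbation_response`` compares optimal vs non-optimal sets on per-gene
log2 fold changes across a perturbation that globally reduces translation
(e.g. viral infection): if codon effects are translation-dependent, the
between-set difference in levels present before the perturbation shrinks
afterwards, which is exactly what the fold-change contrast measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_codons import CodonCompositionMatrix

__all__ = [
    "OptimalityScores",
    "GeneSetContrast",
    "score_genes",
    "select_extremes",
    "contrast_sets",
    "m6a_style_contrast",
    "perturbation_response",
    "read_metric_tsv",
    "read_flags_tsv",
]


@dataclass
class GeneSetContrast:
    """Result of a two-group comparison on a per-gene metric."""

    set_a: str
    set_b: str
    n_a: int
    n_b: int
    metric: str
    test: str
    statistic: float
    p: float
    direction: str  # e.g. "B>A"

    def as_row(self) -> dict:
        return {
            "metric": self.metric,
            "test": self.test,
            "set_a": self.set_a,
            "set_b": self.set_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "statistic": self.statistic,
            "p": self.p,
            "direction": self.direction,
        }


def score_genes(comp: CodonCompositionMatrix, csc: pd.DataFrame) -> pd.DataFrame:
    """Per-gene optimality: weighted-mean CSC and percent-optimal codons.

    Codons with NA CSC are excluded from the weighted sum and the weights
    renormalized over the remaining codons.
    """
    w = csc["r"].astype(float)
    valid = w.index[w.notna()]
    if len(valid) == 0:
        raise ValueError("CSC table is all-NA; cannot score genes")
    F = comp.freq[list(valid)]
    denom = F.sum(axis=1)
    if (denom == 0).any():
        bad = list(comp.freq.index[denom == 0])
        raise ValueError(f"gene(s) composed entirely of NA-CSC codons: {bad[:5]}")
    score = (F @ w[valid]) / denom
    positive = [c for c in valid if w[c] > 0]
    percent_optimal = comp.freq[positive].sum(axis=1) if positive else pd.Series(
        0.0, index=comp.freq.index
    )
    return pd.DataFrame(
        {"score": score, "percent_optimal": percent_optimal}, index=comp.freq.index
    )


def select_extremes(
    scores: pd.Series, n: int = 500
) -> tuple[list[str], list[str]]:
    """Top-n and bottom-n genes by score; ties broken by gene_id so the
    selection is stable across runs."""
    s = scores.dropna()
    if len(s) < 2 * n:
        raise ValueError(f"need at least {2 * n} scored genes; have {len(s)}")
    order = s.to_frame("score").reset_index()
    order.columns = ["gene_id", "score"]
    top = order.sort_values(["score", "gene_id"], ascending=[False, True])
    bottom = order.sort_values(["score", "gene_id"], ascending=[True, True])
    return list(top["gene_id"].head(n)), list(bottom["gene_id"].head(n))


def _two_groups(
    metric: pd.Series, set_a: Sequence[str], set_b: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    if set(set_a) & set(set_b):
        raise ValueError("gene sets must be disjoint")
    a = metric.reindex(list(set_a)).dropna().to_numpy(dtype=float)
    b = metric.reindex(list(set_b)).dropna().to_numpy(dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each set needs >= 3 genes with metric values")
    return a, b


def contrast_sets(
    metric: pd.Series,
    set_a: Sequence[str],
    set_b: Sequence[str],
    test: str = "wilcoxon",
    labels: tuple[str, str] = ("A", "B"),
    metric_name: str = "metric",
) -> GeneSetContrast:
    """Two-sample comparison of a per-gene metric between disjoint gene sets.

    ``wilcoxon``: Mann-Whitney rank-sum.  ``ks``: two-sample
    Kolmogorov-Smirnov.  ``linear``: OLS of the metric on the set-B
    indicator; the statistic is the coefficient, i.e. mean(B) - mean(A),
    with the standard two-sample (equal-variance) t p-value.
    """
    a, b = _two_groups(metric, set_a, set_b)
    if test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        statistic, p = float(res.statistic), float(res.pvalue)
        direction = f"{labels[1]}>{labels[0]}" if np.median(b) > np.median(a) else f"{labels[0]}>{labels[1]}"
    elif test == "ks":
        res = stats.ks_2samp(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
        direction = f"{labels[1]}>{labels[0]}" if np.median(b) > np.median(a) else f"{labels[0]}>{labels[1]}"
    elif test == "linear":
        coef = float(b.mean() - a.mean())
        res = stats.ttest_ind(b, a, equal_var=True)
        statistic, p = coef, float(res.pvalue)
        direction = f"{labels[1]}>{labels[0]}" if coef > 0 else f"{labels[0]}>{labels[1]}"
    else:
        raise ValueError(f"unknown test {test!r}")
    return GeneSetContrast(
        set_a=labels[0],
        set_b=labels[1],
        n_a=a.size,
        n_b=b.size,
        metric=metric_name,
        test=test,
        statistic=statistic,
        p=p,
        direction=direction,
    )


def m6a_style_contrast(
    scaled_decay: pd.Series,
    target_flags: pd.Series,
    mode: str = "endogenous",
) -> dict[str, GeneSetContrast]:
    """Scaled-decay difference between UTR-regulation targets and controls.

    Reports the linear-model difference (the primary statistic) and the KS
    comparison of the two distributions, labelled by assay mode.  In a
    shared-UTR (ORFome) design the UTR-borne destabilization is absent by
    construction, so the same genes show an attenuated difference there.
    """
    flags = target_flags.reindex(scaled_decay.index)
    targets = list(scaled_decay.index[flags == True])  # noqa: E712
    controls = list(scaled_decay.index[flags == False])  # noqa: E712
    if not targets or not controls:
        raise ValueError("both target and control groups must be non-empty")
    common = dict(labels=("control", "target"), metric_name=f"scaled_decay_{mode}")
    return {
        "linear": contrast_sets(scaled_decay, controls, targets, test="linear", **common),
        "ks": contrast_sets(scaled_decay, controls, targets, test="ks", **common),
    }


def perturbation_response(
    levels_before: pd.Series,
    levels_after: pd.Series,
    optimal_set: Sequence[str],
    nonoptimal_set: Sequence[str],
    pseudocount: float = 1.0,
) -> dict:
    """Optimal vs non-optimal comparison across a perturbation.

    Returns per-gene log2 fold changes, the Wilcoxon contrast of fold
    changes between the sets (the dampening test: a significant result with
    optimal < non-optimal means the pre-existing between-set level
    difference shrank), and the between-set median log2-level difference
    before and after.
    """
    genes = levels_before.index.intersection(levels_after.index)
    lb = np.log2(levels_before.loc[genes].astype(float) + pseudocount)
    la = np.log2(levels_after.loc[genes].astype(float) + pseudocount)
    fc = la - lb
    fc.name = "log2fc"
    contrast = contrast_sets(
        fc,
        optimal_set,
        nonoptimal_set,
        test="wilcoxon",
        labels=("optimal", "nonoptimal"),
        metric_name="log2fc",
    )
    opt = [g for g in optimal_set if g in genes]
    non = [g for g in nonoptimal_set if g in genes]
    diff_before = float(lb.loc[opt].median() - lb.loc[non].median())
    diff_after = float(la.loc[opt].median() - la.loc[non].median())
    return {
        "log2fc": fc,
        "contrast": contrast,
        "diff_before": diff_before,
        "diff_after": diff_after,
        "dampened": abs(diff_after) < abs(diff_before),
    }


def read_metric_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, value) -> Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def read_flags_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, 0/1) -> boolean Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(int).astype(bool)
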