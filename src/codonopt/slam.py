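"""SLAM-seq chase kinetics: T->C conversion fractions and half-life fits.

During metabolic labeling, incorporated 4-thiouridine is chemically
derivatized so sequencing reads it as C; after the label is washed out, the
per-gene fraction of T positions read as C decays as labeled transcripts are
replaced by unlabeled ones.  With background conversion rate ``b`` the
corrected fraction follows f(t) = f0 * exp(-k t), so the fit is the same
log-linear OLS used for shutoff time courses (shared core:
:func:`codonopt.decay_kinetics.ols_line`).

To keep the logarithm defined after background subtraction, corrected
fractions are floored at half of the smallest positive corrected fraction of
the gene, which preserves the rank of late timepoints.  Genes failing the
slope p < alpha cutoff are flagged, not removed; removal is a downstream
choice (``filter_significant``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decay_kinetics import ESTIMATE_COLUMNS, ols_line

__all__ = [
    "ConversionTable",
    "ConversionFractions",
    "read_conversion_tsv",
    "write_conversion_tsv",
    "conversion_fractions",
    "estimate_background",
    "fit_slam_decay",
    "filter_significant",
]

_COL_RE = re.compile(r"^t(?P<time>\d+(?:\.\d+)?)_r(?P<rep>\w+)_(?P<kind>cov|tc)$")


@dataclass
class ConversionTable:
    """Per-gene, per-sample T coverage and T->C conversion counts.

    ``t_coverage`` and ``tc_count`` are genes x samples frames with matching
    columns; ``times`` gives chase hours per column.  An optional no-s4U
    control sample (per-gene coverage/conversions) carries the background.
    """

    t_coverage: pd.DataFrame
    tc_count: pd.DataFrame
    times: np.ndarray
    replicates: list[str]
    control_cov: pd.Series | None = None
    control_tc: pd.Series | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if list(self.t_coverage.columns) != list(self.tc_count.columns):
            raise ValueError("coverage and conversion columns must match")
        if np.any(self.times < 0):
            raise ValueError("chase times must be non-negative")
        if (self.tc_count.to_numpy() > self.t_coverage.to_numpy()).any():
            raise ValueError("tc_count exceeds t_coverage")

    @property
    def genes(self) -> list[str]:
        return list(self.t_coverage.index)


@dataclass
class ConversionFractions:
    """Masked conversion fractions (NaN where coverage was insufficient)."""

    fractions: pd.DataFrame
    times: np.ndarray
    background: float = 0.0


def read_conversion_tsv(path: str | Path) -> ConversionTable:
    """Read a TSV with paired columns ``t<h>_r<rep>_cov`` / ``t<h>_r<rep>_tc``
    and optional ``control_cov`` / ``control_tc``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cov_cols, tc_cols, times, reps = [], [], [], []
    for col in df.columns:
        if col in ("control_cov", "control_tc"):
            continue
        m = _COL_RE.match(col)
        if m is None:
            raise ValueError(f"unrecognized SLAM column {col!r}")
        if m.group("kind") == "cov":
            cov_cols.append(col)
            times.append(float(m.group("time")))
            reps.append(m.group("rep"))
        else:
            tc_cols.append(col)
    sample_names = [c[: -len("_cov")] for c in cov_cols]
    expected_tc = [s + "_tc" for s in sample_names]
    if sorted(tc_cols) != sorted(expected_tc):
        raise ValueError("cov/tc column pairs do not match")
    cov = df[cov_cols].copy()
    cov.columns = sample_names
    tc = df[expected_tc].copy()
    tc.columns = sample_names
    return ConversionTable(
        t_coverage=cov,
        tc_count=tc,
        times=np.asarray(times),
        replicates=reps,
        control_cov=df["control_cov"] if "control_cov" in df else None,
        control_tc=df["control_tc"] if "control_tc" in df else None,
    )


def write_conversion_tsv(ct: ConversionTable, path: str | Path) -> None:
    out = {}
    for col, t, r in zip(ct.t_coverage.columns, ct.times, ct.replicates):
        out[f"{col}_cov"] = ct.t_coverage[col]
        out[f"{col}_tc"] = ct.tc_count[col]
    df = pd.DataFrame(out, index=ct.t_coverage.index)
    if ct.control_cov is not None:
        df["control_cov"] = ct.control_cov
        df["control_tc"] = ct.control_tc
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def conversion_fractions(
    ct: ConversionTable, min_coverage: int = 50
) -> ConversionFractions:
    """Elementwise tc/coverage, masking cells below ``min_coverage`` T positions.

    Genes with every cell masked are excluded with a warning.
    """
    cov = ct.t_coverage.to_numpy(dtype=float)
    tc = ct.tc_count.to_numpy(dtype=float)
    mask = cov >= min_coverage
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(mask, tc / np.where(cov > 0, cov, np.nan), np.nan)
    fdf = pd.DataFrame(frac, index=ct.t_coverage.index, columns=ct.t_coverage.columns)
    dead = fdf.isna().all(axis=1)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} gene(s) with no usable SLAM cell excluded",
            stacklevel=2,
        )
        fdf = fdf.loc[~dead]
    return ConversionFractions(fractions=fdf, times=ct.times.copy())


def estimate_background(
    ct: ConversionTable, mode: str = "control", constant: float = 1e-4
) -> float:
    """Background T->C rate: pooled control-sample rate, or a user constant."""
    if mode == "floor-constant":
        return float(constant)
    if mode != "control":
        raise ValueError(f"unknown background mode {mode!r}")
    if ct.control_cov is None or ct.control_tc is None:
        raise ValueError("control-sample background requested but no control present")
    total_cov = float(ct.control_cov.sum())
    if total_cov <= 0:
        raise ValueError("control sample has zero coverage")
    return float(ct.control_tc.sum()) / total_cov


def _wls_line(x, y, w):
    """Weighted simple regression; p from the weighted residual t-test."""
    from scipy import stats as _stats

    w = w / w.sum()
    xm, ym = float(w @ x), float(w @ y)
    sxx = float(w @ (x - xm) ** 2)
    slope = float(w @ ((x - xm) * (y - ym))) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float(w @ resid**2)
    ss_tot = float(w @ (y - ym) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df = x.size - 2
    if df <= 0 or ss_res <= 0:
        return slope, intercept, r2, 0.0 if slope != 0 else 1.0
    se = np.sqrt(ss_res / df / sxx)
    p = 2.0 * _stats.t.sf(abs(slope / se), df)
    return slope, intercept, r2, float(p)


def fit_slam_decay(
    cf: ConversionFractions,
    background: float = 0.0,
    alpha: float = 0.05,
    coverage_weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OLS of ln(background-corrected fraction) on chase hours per gene.

    rate_k = -slope; half_life = ln2/k.  The per-gene floor is half the
    smallest positive corrected fraction.  Genes with no positive corrected
    fraction, or fewer than two usable distinct chase times, are marked
    invalid.  Genes with p_slope >= alpha get flag ``nonsignificant``.
    Passing the coverage table as ``coverage_weights`` switches to
    coverage-weighted least squares (off by default).
    """
    if not 0.0 <= background < 1.0:
        raise ValueError("background rate must be in [0, 1)")
    x_all = np.asarray(cf.times, dtype=float)
    F = cf.fractions.to_numpy(dtype=float)
    corrected = F - background
    W = (
        coverage_weights.reindex(cf.fractions.index)[cf.fractions.columns].to_numpy(
            dtype=float
        )
        if coverage_weights is not None
        else None
    )
    out = pd.DataFrame(index=cf.fractions.index, columns=ESTIMATE_COLUMNS)
    out.index.name = "gene_id"
    for i, gene in enumerate(cf.fractions.index):
        row = corrected[i]
        use = np.isfinite(row)
        pos = row[use & (row > 0)]
        if pos.size == 0 or np.unique(x_all[use]).size < 2:
            out.iloc[i] = [np.nan, np.nan, np.nan, np.nan, np.nan, int(use.sum()), "invalid"]
            continue
        floor = pos.min() / 2.0
        y = np.log(np.maximum(row[use], floor))
        if W is not None:
            s, it, rr, pp = _wls_line(x_all[use], y, W[i, use])
            slope, intercept, r2, p = [s], [it], [rr], [pp]
        else:
            slope, intercept, r2, p = ols_line(x_all[use], y[None, :])
        k = -slope[0]
        out.iloc[i] = [
            k,
            np.log(2.0) / k if k > 0 else np.inf,
            intercept[0],
            r2[0],
            p[0],
            int(use.sum()),
            "",
        ]
    k = out["rate_k"].astype(float)
    p = out["p_slope"].astype(float)
    flags = out["flags"].astype(str)
    nonsig = (flags == "") & ~(p < alpha)
    flags[nonsig] = "nonsignificant"
    flags[(flags == "") & (k < 0)] = "negative_rate"
    out["flags"] = flags
    for col in ("rate_k", "half_life", "intercept", "r2", "p_slope"):
        out[col] = out[col].astype(float)
    out["n_points"] = out["n_points"].astype(int)
    return out


def filter_significant(estimates: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Genes whose slope p-value is strictly below ``alpha``."""
    p = estimates["p_slope"].astype(float)
    return list(estimates.index[p < alpha])
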