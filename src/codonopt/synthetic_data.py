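"""Ground-truth-known synthetic transcriptome decay data.

Every assay design the analysis consumes is emulated here with known
per-codon effects, so that each stage of the pipeline — and the pipeline end
to end — can be checked against truth without external data:

* a synthetic transcriptome: per-gene codon frequencies drawn from a
  symmetric Dirichlet, emitted as real CDS strings (ATG ... TAA) and
  re-counted through :mod:`codonopt.sequence_codons` so the composition
  matrix is a genuine round trip, not a copy of the draw;
* codon-driven first-order decay rates: ln k = ln k0 - sum_c effect_c *
  occurrence_gc + noise, where occurrence is measured in codons per 100
  codons and positive effects are stabilizing (optimal codons lower the
  rate);
* shutoff time courses with log-normal steady-state levels (narrow level
  dispersion in the shared-promoter ORFome design, wide for endogenous
  genes), negative-binomial count sampling, and an m6A-like UTR-borne extra
  decay applied to flagged targets in endogenous mode only;
* SLAM-seq chase tables with binomial T->C conversion counts around
  f(t) = b + (p_inc - b) exp(-k t) plus a no-s4U control at the background
  error rate;
* a perturbation (global translation reduction) that scales all codon
  effects by a dampening factor lambda, moving every rate toward k0.

All draws descend from the scenario seed through named substreams, so a
scenario is reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .decay_kinetics import ExpressionTimeCourse, write_timecourse_tsv
from .sequence_codons import (
    SENSE_CODONS,
    CodingSequence,
    CodonCompositionMatrix,
    build_composition,
    write_composition_tsv,
)
from .slam import ConversionTable, write_conversion_tsv

__all__ = [
    "SimScenario",
    "SimBundle",
    "simulate_effects",
    "simulate_transcriptome",
    "assign_rates",
    "assign_targets",
    "simulate_timecourse",
    "simulate_slam",
    "simulate_perturbation",
    "simulate_all",
    "write_sim_outputs",
]

# substream tags hashed with the scenario seed (SeedSequence spawn keys)
_STREAMS = {
    "effects": 0,
    "transcriptome": 1,
    "rates": 2,
    "targets": 3,
    "timecourse_endogenous": 4,
    "timecourse_orfome": 5,
    "slam": 6,
    "perturbation": 7,
}

#: occurrence unit in the rate model: codons per 100 codons.  Per-codon
#: effects are per percentage point of codon content, the common unit of
#: codon-usage tables; with the default Dirichlet concentration this puts
#: the codon-driven spread of ln k on the same scale as the log-rate noise.
OCCURRENCE_SCALE = 100.0


@dataclass
class SimScenario:
    """Study conditions of a simulation run.

    Defaults mirror the assay designs being emulated: 3000 genes of 100-500
    codons, duplicate samples every hour for 6 h after shutoff, SLAM chase
    at 0/2/4/6 h in triplicate, 2e7 counts per sample, NB dispersion 0.05
    (variance mu + alpha mu^2), baseline rate 0.2/h (half-life ~3.5 h),
    per-codon effect scale 0.05 and log-rate noise sd 0.3.  The ORFome mode
    uses a level dispersion one third of the endogenous one (shared
    promoter/UTRs) and carries no UTR-borne target effect.
    """

    n_genes: int = 3000
    min_codons: int = 100
    max_codons: int = 500
    concentration: float = 5.0
    base_weights: dict[str, float] | None = None  # per-codon Dirichlet weights
    effect_scale: float = 0.05
    k0: float = 0.2  # per hour
    noise_sd: float = 0.3  # sd of Normal noise on ln k
    times: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6)
    replicates: int = 2
    depth: float | None = 2e7  # expected total counts per sample; None = noiseless
    nb_dispersion: float = 0.05  # alpha in var = mu + alpha mu^2; 0 = Poisson
    mode: str = "endogenous"  # or "orfome"
    level_sdlog_endogenous: float = 1.0
    level_sdlog_orfome: float = 1.0 / 3.0
    m6a_target_fraction: float = 0.2
    m6a_decay_shift_sd: float = 0.5  # added ln-rate, in units of sd(ln k)
    slam_times: tuple[float, ...] = (0, 2, 4, 6)
    slam_replicates: int = 3
    slam_coverage: float = 500.0  # expected T positions per gene per sample
    p_inc: float = 0.08  # T->C conversion rate of fully labeled mRNA
    background: float = 1e-4  # T->C error rate without label
    perturbation_lambda: float = 0.3
    level_noise_sdlog: float = 0.1  # measurement noise on perturbation levels
    seed: int = 7

    def level_sdlog(self, mode: str | None = None) -> float:
        mode = mode or self.mode
        if mode == "endogenous":
            return self.level_sdlog_endogenous
        if mode == "orfome":
            return self.level_sdlog_orfome
        raise ValueError(f"unknown mode {mode!r}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


@dataclass
class SimBundle:
    """Everything one scenario produces, keyed for downstream stages."""

    scenario: SimScenario
    effects: pd.Series
    cds: list[CodingSequence]
    composition: CodonCompositionMatrix
    rates: pd.Series
    targets: pd.Series
    timecourse_endogenous: ExpressionTimeCourse
    timecourse_orfome: ExpressionTimeCourse
    slam: ConversionTable
    perturbation_before: pd.Series
    perturbation_after: pd.Series


def simulate_effects(seed: int, scale: float = 0.05) -> pd.Series:
    """61 per-codon effects ~ Normal(0, scale), centered to exact mean 0."""
    if scale <= 0:
        raise ValueError("effect scale must be positive")
    rng = np.random.default_rng([int(seed), _STREAMS["effects"]])
    e = rng.normal(0.0, scale, len(SENSE_CODONS))
    e -= e.mean()
    return pd.Series(e, index=list(SENSE_CODONS), name="effect")


def _largest_remainder(p: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by proportions ``p`` (deterministic)."""
    quota = p * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def simulate_transcriptome(
    scn: SimScenario,
) -> tuple[list[CodingSequence], CodonCompositionMatrix]:
    """Draw per-gene codon proportions and emit real CDS strings.

    Emission is deterministic from integer codon counts (largest-remainder
    apportionment of the Dirichlet draw), so re-counting the emitted CDS
    reproduces the intended composition exactly.  Codon order within a CDS
    carries no information for any statistic computed here.
    """
    if scn.max_codons < scn.min_codons or scn.min_codons < 3:
        raise ValueError("degenerate CDS length distribution")
    rng = scn.rng("transcriptome")
    if scn.base_weights is None:
        alpha = np.full(len(SENSE_CODONS), scn.concentration)
    else:
        w = np.array([scn.base_weights.get(c, 1.0) for c in SENSE_CODONS], dtype=float)
        alpha = scn.concentration * len(SENSE_CODONS) * (w / w.sum())
    lengths = rng.integers(scn.min_codons, scn.max_codons + 1, scn.n_genes)
    props = rng.dirichlet(alpha, scn.n_genes)
    width = len(str(scn.n_genes))
    cds_list = []
    for i in range(scn.n_genes):
        body = _largest_remainder(props[i], int(lengths[i]) - 2)
        seq = "ATG" + "".join(
            c * int(n) for c, n in zip(SENSE_CODONS, body)
        ) + "TAA"
        cds_list.append(CodingSequence(gene_id=f"g{i + 1:0{width}d}", seq=seq))
    comp = build_composition(cds_list)
    return cds_list, comp


def assign_rates(
    comp: CodonCompositionMatrix, effects: pd.Series, scn: SimScenario
) -> pd.Series:
    """Per-gene true rates: ln k = ln k0 - occurrence . effects + noise.

    Occurrence is codon frequency in percent (see ``OCCURRENCE_SCALE``);
    positive effects stabilize (lower k).
    """
    rng = scn.rng("rates")
    occ = comp.freq[list(effects.index)].to_numpy(dtype=float) * OCCURRENCE_SCALE
    signal = occ @ effects.to_numpy(dtype=float)
    lnk = np.log(scn.k0) - signal + rng.normal(0.0, scn.noise_sd, len(comp.genes))
    return pd.Series(np.exp(lnk), index=comp.freq.index, name="rate_k")


def assign_targets(scn: SimScenario, genes: pd.Index | list[str]) -> pd.Series:
    """m6A-like UTR-target flags at the scenario target fraction."""
    rng = scn.rng("targets")
    flags = rng.random(len(genes)) < scn.m6a_target_fraction
    return pd.Series(flags, index=list(genes), name="m6a_target")


def simulate_timecourse(
    rates: pd.Series,
    scn: SimScenario,
    mode: str | None = None,
    targets: pd.Series | None = None,
) -> ExpressionTimeCourse:
    """Shutoff time-course counts around L_g * exp(-k_g t).

    The count scale is depth / sum(levels), constant across timepoints (as
    for a spike-in-normalized table), so fitted slopes estimate the true
    rates directly.  In endogenous mode flagged targets decay faster by
    ``m6a_decay_shift_sd`` standard deviations of ln k; in ORFome mode the
    shared UTR removes that effect and level dispersion is narrow.
    ``depth=None`` emits exact expected values (noiseless limit).
    """
    mode = mode or scn.mode
    if 0.0 not in [float(t) for t in scn.times]:
        raise ValueError("timepoints must include 0")
    rng = scn.rng(f"timecourse_{mode}")
    k = rates.to_numpy(dtype=float).copy()
    if mode == "endogenous" and targets is not None and scn.m6a_decay_shift_sd:
        shift = scn.m6a_decay_shift_sd * np.log(rates).std(ddof=1)
        k = k * np.where(targets.reindex(rates.index).to_numpy(), np.exp(shift), 1.0)
    levels = rng.lognormal(0.0, scn.level_sdlog(mode), k.size)
    scale = (scn.depth if scn.depth is not None else 1e6) / levels.sum()
    cols, data = [], []
    for t in scn.times:
        mu = scale * levels * np.exp(-k * float(t))
        for r in range(1, scn.replicates + 1):
            cols.append(f"t{_fmt(t)}_r{r}")
            if scn.depth is None:
                data.append(mu)
            elif scn.nb_dispersion > 0:
                nshape = 1.0 / scn.nb_dispersion
                data.append(rng.negative_binomial(nshape, nshape / (nshape + mu)))
            else:
                data.append(rng.poisson(mu))
    values = pd.DataFrame(
        np.column_stack(data), index=rates.index, columns=cols, dtype=float
    )
    times = np.repeat([float(t) for t in scn.times], scn.replicates)
    reps = [c.split("_r")[1] for c in cols]
    return ExpressionTimeCourse(values=values, times=times, replicates=reps)


def simulate_slam(rates: pd.Series, scn: SimScenario) -> ConversionTable:
    """Binomial T->C chase counts with Poisson T coverage and a no-s4U control."""
    if scn.p_inc <= scn.background:
        raise ValueError("incorporation rate must exceed background")
    if 0.0 not in [float(t) for t in scn.slam_times]:
        raise ValueError("chase timepoints must include 0")
    rng = scn.rng("slam")
    k = rates.to_numpy(dtype=float)
    b = scn.background
    cov_cols, tc_cols, names = [], [], []
    for t in scn.slam_times:
        f = b + (scn.p_inc - b) * np.exp(-k * float(t))
        for r in range(1, scn.slam_replicates + 1):
            cov = rng.poisson(scn.slam_coverage, k.size)
            tc = rng.binomial(cov, f)
            names.append(f"t{_fmt(t)}_r{r}")
            cov_cols.append(cov)
            tc_cols.append(tc)
    control_cov = rng.poisson(scn.slam_coverage, k.size)
    control_tc = rng.binomial(control_cov, b)
    idx = rates.index
    return ConversionTable(
        t_coverage=pd.DataFrame(np.column_stack(cov_cols), index=idx, columns=names),
        tc_count=pd.DataFrame(np.column_stack(tc_cols), index=idx, columns=names),
        times=np.repeat([float(t) for t in scn.slam_times], scn.slam_replicates),
        replicates=[c.split("_r")[1] for c in names],
        control_cov=pd.Series(control_cov, index=idx, name="control_cov"),
        control_tc=pd.Series(control_tc, index=idx, name="control_tc"),
    )


def simulate_perturbation(
    comp: CodonCompositionMatrix,
    effects: pd.Series,
    scn: SimScenario,
    lam: float | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Steady-state level tables before and after codon-effect dampening.

    Levels are proportional to 1/k (constant synthesis, first-order decay).
    After the perturbation the codon effects are multiplied by lambda in
    [0, 1] — rates move toward k0 — while the gene-specific rate noise is
    shared between the two states, so lambda = 1 reproduces the before
    state exactly up to measurement noise.
    """
    lam = scn.perturbation_lambda if lam is None else lam
    if not 0.0 <= lam <= 1.0:
        raise ValueError("dampening factor must be in [0, 1]")
    rng = scn.rng("perturbation")
    occ = comp.freq[list(effects.index)].to_numpy(dtype=float) * OCCURRENCE_SCALE
    signal = occ @ effects.to_numpy(dtype=float)
    noise = rng.normal(0.0, scn.noise_sd, len(comp.genes))
    k_before = np.exp(np.log(scn.k0) - signal + noise)
    k_after = np.exp(np.log(scn.k0) - lam * signal + noise)
    base = 1000.0 * scn.k0  # arbitrary expression units
    before = base / k_before * rng.lognormal(0.0, scn.level_noise_sdlog, k_before.size)
    after = base / k_after * rng.lognormal(0.0, scn.level_noise_sdlog, k_after.size)
    idx = comp.freq.index
    return (
        pd.Series(before, index=idx, name="level_before"),
        pd.Series(after, index=idx, name="level_after"),
    )


def simulate_all(scn: SimScenario) -> SimBundle:
    """Run every simulator of the scenario and bundle the outputs."""
    effects = simulate_effects(scn.seed, scn.effect_scale)
    cds, comp = simulate_transcriptome(scn)
    rates = assign_rates(comp, effects, scn)
    targets = assign_targets(scn, comp.freq.index)
    tc_endo = simulate_timecourse(rates, scn, mode="endogenous", targets=targets)
    tc_orf = simulate_timecourse(rates, scn, mode="orfome", targets=targets)
    slam_table = simulate_slam(rates, scn)
    before, after = simulate_perturbation(comp, effects, scn)
    return SimBundle(
        scenario=scn,
        effects=effects,
        cds=cds,
        composition=comp,
        rates=rates,
        targets=targets,
        timecourse_endogenous=tc_endo,
        timecourse_orfome=tc_orf,
        slam=slam_table,
        perturbation_before=before,
        perturbation_after=after,
    )


def write_sim_outputs(bundle: SimBundle, outdir: str | Path) -> list[Path]:
    """Write the canonical simulation files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _w(name: str, fn) -> None:
        p = outdir / name
        fn(p)
        paths.append(p)

    def _fasta(p: Path) -> None:
        with open(p, "w") as fh:
            for cds in bundle.cds:
                fh.write(f">{cds.gene_id}\n")
                for i in range(0, len(cds.seq), 60):
                    fh.write(cds.seq[i : i + 60] + "\n")

    _w("cds.fasta", _fasta)
    _w("composition.tsv", lambda p: write_composition_tsv(bundle.composition, p))
    _w(
        "truth_effects.tsv",
        lambda p: bundle.effects.rename_axis("codon").to_csv(
            p, sep="\t", float_format="%.10g"
        ),
    )
    _w(
        "truth_rates.tsv",
        lambda p: bundle.rates.rename_axis("gene_id").to_csv(
            p, sep="\t", float_format="%.10g"
        ),
    )
    _w(
        "timecourse_endogenous.tsv",
        lambda p: write_timecourse_tsv(bundle.timecourse_endogenous, p),
    )
    _w(
        "timecourse_orfome.tsv",
        lambda p: write_timecourse_tsv(bundle.timecourse_orfome, p),
    )
    _w("slam_conversions.tsv", lambda p: write_conversion_tsv(bundle.slam, p))
    _w(
        "m6a_flags.tsv",
        lambda p: bundle.targets.astype(int).rename_axis("gene_id").to_csv(p, sep="\t"),
    )
    _w(
        "perturbation_before_after.tsv",
        lambda p: pd.DataFrame(
            {
                "level_before": bundle.perturbation_before,
                "level_after": bundle.perturbation_after,
            }
        )
        .rename_axis("gene_id")
        .to_csv(p, sep="\t", float_format="%.10g"),
    )
    return paths


def _fmt(t: float) -> str:
    t = float(t)
    return str(int(t)) if t == int(t) else str(t)
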