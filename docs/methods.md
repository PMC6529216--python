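# Methods

## Decay model and fitting

All three assay designs are reduced to the same statistical core: first-order
decay, `N(t) = N(0) e^(-kt)`, fitted as ordinary least squares of the natural
log of the observable against hours.  For shutoff time courses the observable
is `value + pseudocount` (default pseudocount 0.5, so zero counts at late
timepoints of fast-decaying genes stay finite); for SLAM-seq it is the
background-corrected T→C conversion fraction.  `rate_k = -slope`,
`half_life = ln 2 / k` (infinite for k ≤ 0), with the slope's two-sided
t-test p-value and R² from the same fit.  One closed-form, vectorized OLS
routine (`decay_kinetics.ols_line`) backs both fits, so their slopes agree
exactly on identical points.

Choices worth stating:

* **Replicates are independent regression points**, never pre-averaged;
  this preserves the residual degrees of freedom behind `p_slope`.
* **Negative fitted rates are kept and flagged**, not truncated at zero.
  Truncation would bias every downstream correlation; an apparent
  stabilization is information about the noise floor.
* **No global decay correction.**  The count scale is assumed constant
  across timepoints (spike-in-like normalization).  A common per-timepoint
  factor shifts every gene's log value equally, hence every slope equally,
  and the CSC — a Pearson correlation, invariant under affine maps of the
  stability vector — is unchanged.  Absolute rates, however, are only as
  good as the input normalization; this is a documented limitation.
* **Zero-variance responses** get slope 0 and p = 1; a perfect non-flat
  fit gets p = 0.  Genes with fewer than two usable distinct times are
  marked invalid rather than dropped silently.

## Expression filtering (zFPKM-style)

Per sample, log2 expression is standardized against the mode of its kernel
density: `z = (log2 x - mu) / sigma` with `sigma = (U - mu) / sqrt(2 ln 2)`,
where U is the abscissa where the density falls to half its peak on the
right (high-expression) side — the left side is contaminated by the
unexpressed tail.  The KDE uses a deliberately wide Gaussian kernel
(bandwidth half the data sd) to stabilize the mode, with quadratic
interpolation of the peak; the smoothing the kernel adds to the half-max
width is removed by deconvolution (`sigma² = sigma_kde² - h²`), since the
KDE of a locally Gaussian peak is that peak convolved with the kernel.
Genes whose mean z across t = 0 replicates is ≤ −3 are excluded before
fitting.  Zeros standardize to −inf and are dropped by any finite
threshold.

## SLAM-seq specifics

Conversion fractions are `tc / coverage`, masked where fewer than 50 T
positions were sequenced.  Background is the pooled rate of a no-s4U
control sample (or a constant, default 1e-4).  After subtraction, fractions
are floored at half the smallest positive corrected fraction of the gene —
this keeps the log defined while preserving the rank of late timepoints.
The model is fitted on the log scale by OLS rather than by nonlinear least
squares on the fraction scale because it matches the first-order linear
treatment used everywhere else and yields a slope p-value directly; the
estimator is validated by parameter recovery (median relative half-life
error ≤ 15% at coverage 500, chase 0/2/4/6 h in triplicate) rather than by
matching any external implementation.  Coverage-weighted OLS exists behind
a flag but is off by default, since no weighting rule is canonical.  Genes
failing p < 0.05 are flagged `nonsignificant`, not removed.

## CSC and ASC

Codon "occurrence" is implemented as per-gene **frequency** (count over
total sense codons), not raw count: a correlation across genes of widely
different CDS lengths would otherwise be dominated by length.  Raw counts
are retained and drive the codon-usage summary and the abundance ranking of
the ASC leave-one-out variant.  Stop codons are excluded from the 61-codon
space; the start codon is counted by default (both are flags).  Internal
premature stops flag the record but do not truncate counting — composition
is a pure sequence property.  Ambiguity codes invalidate a record whole; a
silently skipped triplet would shift every frequency.

CSC: Pearson r per codon against stability over the gene intersection,
pairwise-complete, minimum 10 genes.  Codons with zero variance or absent
from >99% of genes are NA, not near-degenerate correlations.  The default
stability convention is −k (defined for all genes); log2 half-life is
available behind a flag (k ≤ 0 excluded there).  Which convention the
correlation uses barely matters in practice because Spearman-level ordering
is preserved, but it is a genuine free choice and therefore exposed.

ASC leave-one-out: the most abundant synonymous codon is determined from
summed raw counts; the reduced amino-acid occurrence is renormalized by
**total** sense codons (not by the remaining synonymous count), so the
reduced column is still a composition fraction of the gene; the alternative
is a flag.  Met and Trp are NA by construction.

tRNA-style covariates can be keyed by anticodon, mapped to codons by exact
Watson-Crick reverse complement only; wobble decoding is deliberately not
modeled.

## Gene sets and contrasts

The per-gene optimality score is the frequency-weighted mean CSC
(renormalized over codons with a defined CSC); the fraction of codons with
positive CSC (`percent_optimal`) is reported alongside, since with equal
CSC magnitudes the two rankings coincide and with real tables they differ
slightly.  Extreme sets are top/bottom n = 500 with lexicographic
tie-breaks for determinism.  Contrasts: Mann-Whitney rank-sum (scipy's
auto policy: exact for small untied samples, corrected normal
approximation otherwise), two-sample KS, or a linear model on the set
indicator whose coefficient is the difference of group means with the
pooled-variance t p-value.  The perturbation analysis compares per-gene
log2 fold changes (pseudocount 1) between optimal and non-optimal sets;
a significant difference with optimal genes falling is the signature of
dampened codon effects, and the between-set median log2-level difference
before vs after is reported explicitly.

## Synthetic data: what it emulates, and what it does not

Per-gene codon proportions are symmetric-Dirichlet (concentration 5 per
codon; an optional per-codon base-weight vector skews usage, e.g. to make
CTG dominant among leucine codons).  CDS strings are emitted
deterministically from largest-remainder integer apportionment of the draw
— `ATG` + body + `TAA` — and the composition matrix is re-counted from the
emitted sequences, so the round trip is exact.  Gene lengths are uniform on
100–500 codons.

True rates: `ln k = ln k0 - Σ_c effect_c · occurrence_gc + Normal(0, 0.3)`
with k0 = 0.2/h and 61 centered effects ~ Normal(0, 0.05).  **Occurrence
enters in codons per 100 codons** (the unit of codon-usage tables): with the
default composition dispersion this puts the codon-driven spread of ln k on
the same scale as the log-rate noise and yields a realistic half-life range
(roughly 1.5–8 h).  Positive effects are stabilizing, matching the sign
convention in which optimal codons correlate positively with stability.

Time courses: steady-state levels are log-normal with sd(log) 1.0 for
endogenous genes and 1/3 of that for the ORFome mode (shared promoter and
UTRs produce the narrower level distribution); expected counts are
`scale · L_g · e^(-k t)` at 2e7 counts per sample, sampled
negative-binomially with dispersion 0.05 (variance μ + αμ²); duplicates at
0–6 h hourly.  m6A-like targets (20% of genes by default) receive an extra
0.5 sd(ln k) of decay **in endogenous mode only** — in the ORFome design the
UTR element does not exist.  `depth=None` emits exact expected values, the
noiseless limit used for oracle tests.

SLAM tables: Poisson T coverage around 500 per gene and sample, binomial
conversions at `b + (p_inc - b) e^(-kt)` with incorporation 0.08 and
background 1e-4, chase 0/2/4/6 h in triplicate, plus a no-s4U control.  The
labeling (feeding) phase is not modeled; only the chase is fitted.

Perturbation: levels are 1/k (constant synthesis) with 0.1 sd(log)
measurement noise; "after" recomputes rates with effects scaled by
λ = 0.3, sharing the per-gene noise term so λ = 1 reproduces the before
state up to measurement noise.

What the generator does **not** emulate: UTR sequences themselves, isoform
structure, length-dependent coverage, transcription during the chase,
batch effects, or any correlation between codon content and expression
level.  Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to real-data pathologies
like incomplete shutoff or composition-correlated confounders.

All simulator draws descend from the scenario seed through named
substreams, so every output is reproducible byte for byte; the pipeline
manifest records sha256 hashes and re-running a config is hash-identical.

## Problem sizes and numerical tolerances

Default analyses and the acceptance script run at 3000 genes (600 for the
two-group contrast scenario, 200 genes for the SLAM rate grid, 1000 for the
leucine construction) — large enough that the recovery statistics are
stable across seeds while a full run completes in seconds.  Closed-form
oracle comparisons are asserted at 1e-9, affine-invariance identities at
1e-12, KDE parameter recovery at 0.1–0.15 absolute, and simulation-based
recovery at the thresholds stated in the test docstrings (rank correlation
≥ 0.9, sign agreement ≥ 85%, median half-life error ≤ 15%), fixed before
the tests were run.

## Known limitations

* Absolute decay rates depend on the input table's normalization; only
  statistics invariant to per-timepoint scaling (CSC, ASC, rank-based
  contrasts) are robust to it.
* The SLAM floor biases late-timepoint fits of very fast-decaying genes
  toward slower rates; the bias is bounded in the recovery tests but grows
  as coverage falls.
* Exact anticodon pairing only; no wobble rules for tRNA covariates.
* Single-exponential kinetics throughout; no degradation-synthesis joint
  modeling, no multi-phase decay.
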