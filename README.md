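# codonopt

Codon-optimality statistics for mRNA stability in human cells.

Synonymous codons are not neutral: beyond specifying amino acids, codon
composition influences how fast an mRNA is degraded, with "optimal" codons
enriched in stable transcripts and "non-optimal" codons in unstable ones.
`codonopt` is a tested, reusable implementation of the analysis used to map
this codon-optimality code from three independent assay designs:

1. **Transcription-shutoff time courses** — expression of endogenous genes
   measured at timed intervals after blocking transcription;
2. **Barcoded ORFome libraries** — thousands of coding sequences sharing one
   promoter and UTRs, each tagged with a unique 3'UTR barcode, which
   isolates coding-sequence effects from UTR-borne regulation;
3. **SLAM-seq metabolic-label chase** — decay measured without blocking
   transcription, from the decline of T→C conversions after washing out a
   4-thiouridine label.

It is aimed at computational RNA biologists who have count/conversion
tables (read alignment and quantification are upstream and out of scope)
and want decay rates, stabilization coefficients and the downstream
gene-set comparisons, with every stage verifiable against a synthetic
ground truth.

## The statistics

For each gene, expression after shutoff follows first-order kinetics,
`N(t) = N(0) e^(-kt)`, so ordinary least squares of `ln(N + pc)` on hours
gives the decay constant `k = -slope` and half-life `t1/2 = ln 2 / k`.
Genes are pre-filtered with a zFPKM-style criterion (density-mode
standardized log2 expression > −3 at t = 0).  SLAM-seq chase data fit the
same log-linear model on background-corrected conversion fractions
`f(t) = f0 e^(-kt)`.

The **codon stabilization coefficient (CSC)** of codon *c* is the Pearson
correlation, across genes, between the per-gene occurrence of *c* (codon
frequency over the 61 sense codons) and mRNA stability (default −k).  The
**amino-acid stabilization coefficient (ASC)** is the same correlation for
amino-acid occurrence, with a leave-one-out variant that recomputes it
after removing each amino acid's most abundant synonymous codon — the
diagnostic for amino acids whose apparent optimality is driven by a single
dominant codon (e.g. leucine's CTG).

Gene sets are scored by frequency-weighted mean CSC; top/bottom-500 sets
feed Wilcoxon / Kolmogorov-Smirnov / linear-model contrasts on stability,
poly(A) status, m6A-target flags, and perturbation fold changes.

The synthetic generator (`codonopt.synthetic_data`) draws per-gene codon
compositions from a Dirichlet, assigns rates by
`ln k = ln k0 - Σ_c effect_c · occurrence_gc + noise` with known effects,
and emits every assay table the analysis consumes, so parameter recovery
can be asserted end to end.

## Worked example

Run the full synthetic pipeline and summarize it:

```sh
codonopt run --outdir out --seed 7 --set n_genes=800
codonopt report --manifest out/manifest.json
```

which prints (abridged):

```
codonopt 0.1.0 run report (seed 7)

csc_endogenous.tsv: 61 codons with defined CSC
  most stabilizing: ACT (0.149), TAT (0.148), TTC (0.142), GAG (0.128), GTG (0.127)
  most destabilizing: CGG (-0.230), CAG (-0.191), GGG (-0.168), CCA (-0.143), CTG (-0.115)

contrasts:
  scaled_decay_endogenous [linear] control vs target: stat=0.4882 p=3.7e-08 (target>control)
  scaled_decay_orfome [linear] control vs target: stat=0.004235 p=0.962 (target>control)
```

Reading this: each codon's CSC is its correlation with stability, so ACT is
the most stabilizing codon in this simulation and CGG the most
destabilizing.  The m6A-style contrast finds that flagged target genes
decay significantly faster than controls in the endogenous assay (linear
model difference of ~0.49 standard deviations of scaled decay, p ≈ 4e-8)
but show no difference in the shared-UTR ORFome assay (p ≈ 0.96) — the
UTR-borne destabilization disappears when all transcripts share the same
UTRs, exactly the behavior the design is meant to isolate.

The individual stages are also available as subcommands (`simulate`,
`decay`, `slam`, `csc`, `asc`, `sets`) operating on TSV tables, and as
library functions (`codonopt.fit_first_order`, `codonopt.compute_csc`,
...).

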