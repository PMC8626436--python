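# meripdiff

Differential N6-methyladenosine (m6A) analysis for MeRIP-seq coverage on
transcript coordinates.

MeRIP-seq profiles mRNA methylation by sequencing an anti-m6A
immunoprecipitated library (IP) alongside its unenriched input. This
package implements the downstream comparative analysis used to find the
mRNA targets of an m6A demethylase from such data: peaks called per
sample are reconciled into a union peak reference, each sample is scored
by its IP-over-input enrichment per peak, peaks whose group-mean scores
shift beyond fixed thresholds are called differentially methylated, and
genes behaving consistently across loss- and gain-of-function conditions
— hypermethylated when the demethylase is knocked down or knocked out,
hypomethylated when it is overexpressed — are reported as its targets.
A synthetic MeRIP-seq generator with a planted truth table makes the
whole pipeline testable end to end without external data.

## The statistics at the core

For a union peak *p* and sample *s* with IP read count
*k*<sub>IP</sub> and input read count *k*<sub>in</sub> inside the peak,
the enrichment score is the library-normalized read ratio

> score(p, s) = (*k*<sub>IP</sub> / *N*<sub>IP</sub>) / (*k*<sub>in</sub> / *N*<sub>in</sub>)

with a 0.5 pseudocount on both counts. For a case/control contrast the
peak's log2 fold change is log2(mean<sub>case</sub> /
mean<sub>control</sub>) of the group-mean scores, and a differentially
methylated peak (DMP) must satisfy

> max(mean<sub>case</sub>, mean<sub>control</sub>) > 6  and  |log2FC| > 1.

Per-sample peaks come from a windowed Poisson test (window IP count
against the library-scaled input count, tail probability < 1e-5,
significant windows merged), peaks overlapping between two samples of a
group form its common peaks, and the case and control groups' common
peaks merge into the union reference the scores are computed on.

Also included: DRACH motif scanning (D=A/G, R=A/G, H=A/C/T) with
A-to-T site-ablation design, metagene profiling over normalized
5'UTR/CDS/3'UTR coordinates, dinucleotide-shuffle k-mer enrichment,
Fisher's-exact set enrichment with Benjamini-Hochberg correction, and
the bench formulas 2^-ΔΔCT, the m6A-IP qPCR Cq ratio, and first-order
mRNA decay half-life (ln 2 / k from a log-linear fit).

## Worked example

```python
import numpy as np
from meripdiff import PipelineConfig, SimulationConfig, run_pipeline, recovery_stats

cfg = PipelineConfig(simulation=SimulationConfig(seed=7))
res = run_pipeline(cfg)          # simulate -> peaks -> DMPs -> targets
stats = recovery_stats(res)
print("planted targets :", stats["n_planted"])
print("recovered       :", stats["true_positives"])
print("sensitivity     :", round(stats["sensitivity"], 3))
print("precision       :", round(stats["precision"], 3))
for label, table in res.dmp_tables.items():
    n = int(table.passed_filters.sum())
    hyper = int((table.passed_filters & (table.status == "hyper")).sum())
    print(f"{label}: {len(table)} union peaks, {n} DMPs ({hyper} hyper, {n-hyper} hypo)")
d, (b5, bc, b3) = res.metagene, res.metagene_bins
print("metagene modal bin:", int(np.argmax(d)), f"(bins {b5} 5'UTR | {bc} CDS | {b3} 3'UTR)")
```

The default design — 300 genes, 30 demethylase targets, groups Ctl, KD,
cKO, OE with two replicates each, a planted log2 effect of 2 — prints:

```
planted targets : 30
recovered       : 29
sensitivity     : 0.967
precision       : 1.0
KD_vs_Ctl: 95 union peaks, 32 DMPs (32 hyper, 0 hypo)
cKO_vs_Ctl: 96 union peaks, 32 DMPs (32 hyper, 0 hypo)
OE_vs_Ctl: 95 union peaks, 31 DMPs (0 hyper, 31 hypo)
metagene modal bin: 69 (bins 20 5'UTR | 50 CDS | 30 3'UTR)
```

29 of the 30 planted target genes carry hypermethylated DMPs in both
loss-of-function contrasts and hypomethylated DMPs in the
overexpression contrast, with no false positives; the metagene mode
sits at the stop codon, where the generator concentrates its sites.

The same pipeline runs from the shell:

```sh
meripdiff run --seed 7 --outdir out/        # full bundle + manifest.json
meripdiff simulate --seed 7 --outdir sim/   # FASTA + TSV + bedGraph tracks
meripdiff dmp --case KD --control Ctl --min-score 6 --min-abs-lfc 1 --out dmp.tsv
meripdiff quant --mode decay --table decay.tsv --out fits.tsv
```

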