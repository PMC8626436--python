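# Methods

## Coordinate model

Everything lives in transcript coordinates: one intron-free,
single-isoform transcript per gene, partitioned into a 5'UTR, CDS and
3'UTR, sense strand only, all intervals 0-based half-open. This removes
genome-scale machinery (intron-aware projection, strand bookkeeping,
multi-isoform ambiguity) while preserving every computation the package
exists for — peak calling against input, union-reference differential
scoring, region annotation, metagene profiling and motif work all
operate on mRNA.

## The synthetic MeRIP-seq generator

The generator emulates a four-group demethylase perturbation study
(control, knockdown, knockout, overexpression; two biological
replicates each by default) with a planted truth table.

**Transcripts.** Region lengths are drawn uniformly from configurable
ranges (defaults 100–300 nt 5'UTR, 300–1500 nt CDS, 200–800 nt 3'UTR);
the sequence background is i.i.d. uniform ACGT, so background DRACH
matches occur at their natural rate and are expected.

**Sites.** A configurable fraction of genes (default 0.30, within the
25–34% range typical of mammalian m6A surveys) is methylated; each
methylated gene receives 1 + Poisson(r − 1) sites (default r = 2.65
expected sites per modified gene). Site positions are placed at the
stop codon plus a truncated-geometric offset into the 3'UTR (mean
80 nt; a uniform mode exists), reproducing the stop-codon-proximal
concentration characteristic of m6A; a random DRACH 5-mer is written
into the sequence at each site, with the methylated A as the recorded
site position.

**Methylation levels and effects.** Non-target methylated genes carry
the same level (default 0.5) in every group. Target genes start at
0.35 in control; perturbed groups multiply this by 2^(±effect_log2fc)
(raised in KD/cKO, lowered in OE; default effect 2), clipped to [0, 1].

**Counts.** Input coverage at every position is the gene's baseline
expression (uniform 5–20 reads/nt at the nominal depth) scaled by
library size; IP coverage multiplies in 1 + (E − 1)·m over ±50 nt
around each site (the span of a ~100-nt MeRIP fragment), where m is
the site's methylation level and E the IP fold-enrichment at full
methylation (default 30). Noise is negative binomial via gamma–Poisson
with dispersion 0.1 by default (variance μ + 0.1 μ²); dispersion 0
degenerates to Poisson. One seeded stream in a documented order
(samples, then transcripts, input before IP) makes runs bit-identical.

The defaults were chosen so the per-peak enrichment scores land where
the downstream thresholds are meaningful in *both* directions: with
E = 30 and ~80% of a called peak covered by the enriched span, control
targets score ≈ 9, knockdown/knockout ≈ 24 and overexpression ≈ 3 —
comfortably across the >6 absolute and |log2FC| > 1 criteria without
saturating the m ≤ 1 ceiling. The recorded library size is the nominal
sequencing depth (25 M reads, identical for IP and input), an upper
bound on the reads assigned to the simulated transcriptome; means
scale linearly with it.

**What the generator does not emulate.** Isoform complexity, genomic
alignment artifacts, fragment-level coverage autocorrelation, GC and
mappability bias, IP-efficiency variation between samples, and
expression changes between groups (input levels are group-invariant).
Passing tests therefore demonstrate correctness of the analysis logic
under a clean count model, not robustness to every failure mode of
real libraries.

## Peak calling

A windowed Poisson test replaces HMM-based exome peak callers: in
non-overlapping 25-nt windows the IP count is tested against a Poisson
null with mean = input count × (N_IP/N_in), floored at a 0.5-read
pseudocount; windows with tail probability < 1e-5 are significant;
significant windows within 50 nt merge; merged regions under 50 nt are
dropped. The summit is the position of maximal per-position normalized
IP/input ratio and the peak score its mean over the peak. Transcripts
under 1 input CPM are treated as unexpressed. No multiple-testing
correction is applied inside the caller — the threshold is an
operating point. Note the Poisson null is anticonservative under
negative-binomial overdispersion; irreproducible single-sample false
positives are expected and are removed downstream by the common-peak
step, which is why "modified genes" should be counted from
replicate-reproducible peaks.

## Differential methylation

Common peaks between two samples are the spanning intervals of
connected overlap components containing at least one peak from each
sample; overlap means ≥ 1 shared nucleotide — exact adjacency does not
join (an intersection mode is available). With more than two replicates
the operation folds pairwise. The union reference merges the groups'
common peaks, joining overlapping or exactly adjacent intervals into a
disjoint sorted list with provenance.

Enrichment scores are library-normalized IP/input read ratios with a
0.5 pseudocount. A peak passes for a contrast when the *higher* of the
two group-mean scores exceeds 6 and |log2FC| of the means (floored at
1e-8) exceeds 1. Requiring the higher mean — rather than both —
keeps a peak callable when one condition erases it entirely; both-group
and pooled-mean modes are provided. The filter is deliberately
threshold-only; replicate-aware statistical testing (GLMs, dispersion
estimation) is out of scope.

## Target discovery and annotation

A gene is a demethylase target when it carries ≥ 1 hypermethylated DMP
in each loss-of-function contrast and ≥ 1 hypomethylated DMP in the
gain-of-function contrast; membership is any-peak per contrast, and
output order is lexicographic. Peaks are annotated by their summit:
within ±50 nt of the CDS/3'UTR boundary is stop-codon vicinity (takes
precedence; the window is configurable), otherwise 5'UTR, CDS or 3'UTR
by position. Union peaks carry no caller summit, so their midpoint
serves as the representative position. Metagene profiles rescale each
region to fixed bin counts (20/50/30) and normalize to unit mass. Set
enrichment is a two-sided Fisher's exact test per category with
Benjamini–Hochberg adjustment across the categories of one call; no
annotation databases are shipped.

## Motif analysis and mutagenesis

DRACH is implemented with the letter sets D = A/G, R = A/G, H = A/C/T
(the definition used by the reporter-assay design this package
validates against, which omits T from the conventional IUPAC D); a
strict-IUPAC mode is available behind a flag. Scanning reports all
overlapping matches. Mutagenesis replaces the central A of selected
hits with T; on the bundled 607-nt wild-type Adrb2 3'UTR reporter
fragment, ablating the four annotated sites reproduces the bundled
mutant fragment byte-for-byte (the wild type contains one additional
background DRACH match that the reporter design left untouched; the
scanner reports all matches and leaves site selection to the caller).
Motif discovery over 100-nt summit-centered windows is approximated by
k-mer counting against Altschul–Erickson dinucleotide-preserving
shuffles (hand-implemented; empirical p = (1 + #{shuffle ≥ observed}) /
(n + 1)). This recovers GGAC-containing enrichment but is not a
positional motif model.

## Quantification formulas

2^-ΔΔCT uses a per-sample ΔCT against the internal-control gene.
The m6A-IP qPCR level defaults to the literal Cq(IP)/Cq(input) cycle
ratio for fidelity to the assay definition it mirrors, with the
conventional percent-of-input 2^(Cq_in − Cq_IP) as an alternative mode
— the literal ratio of cycle numbers is unusual, and both readouts are
exposed deliberately. Decay half-life is ln 2 / k with k from an
ordinary least-squares fit of ln(abundance) on time — exact on exact
exponentials and the standard choice for a three-point time course;
non-decaying fits return an infinite half-life with a flag rather than
an error.

## Problem sizes and numerical choices

The default study design (300 genes, 30 targets, 8 samples, ~800 kb of
simulated transcriptome) runs the full pipeline in a few seconds and
is the size at which the recovery properties are stated. Oracle checks
use 1,000 random instances each. Ties in top-peak selection break by
(transcript, start); window argmax takes the first maximum; degenerate
inputs (empty peak lists, zero-length regions, zero library sizes,
non-positive abundances) raise ValueError rather than propagating NaN.
All randomness flows from a single integer seed through documented
child streams.

## Known limitations

The peak caller claims no equivalence with HMM-based callers. The DMP
filter has no error control across peaks. The any-peak membership rule
for targets can link a gene through different peaks in different
contrasts. The generator's clean count model understates real-data
variability, and enrichment scores assume IP and input depths are
comparable after library-size normalization — transcriptome-wide
composition shifts between IP libraries are not modeled.
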