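# Methods

This note documents the statistical models, defaults, and design
choices behind each pipeline stage, the assumptions of the synthetic
data generator, and what the validation suite does and does not
establish about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward genomic
strand. GTF (1-based inclusive) is converted at the parsing boundary;
BED is used natively. A CLIP tag's 5′ end — the truncation-site proxy —
is `start` on the + strand and `end − 1` on the − strand. Exons with
identical coordinates in different transcripts are one exon entity;
partially overlapping variants (alternative 5′/3′ splice sites) remain
distinct exons. When two annotated genes overlap a position, lookups
take the first same-strand gene containing it. Sequence windows are
always reported in transcript orientation (reverse-complemented on −,
T transcribed to U).

## Cluster calling

Candidate clusters are maximal runs of overlapping tags per
chromosome and strand (replicate tags pooled). The null model is
gene-local and Poisson: λ_g = (tags assigned to the gene) / (gene
span length), so a candidate of width w and n tags gets
p = P(Pois(λ_g·w) ≥ n). Tags outside annotated genes share a single
intergenic rate; a cluster straddling a gene boundary uses the
most-overlapped same-strand gene. Bonferroni correction uses the
number of candidate clusters genome-wide — the most conservative
defensible scope — and clusters pass at corrected p < 0.05
(`cluster_alpha`). Because planted/real clusters inflate λ_g, the test
is conservative for genes that carry strong binding; this costs little
at the signal strengths of interest (p-values are astronomically
small) and protects the null calibration.

## CITS calling

Within each significant cluster of n tags and width w, the number of
5′ ends at a position is compared against a uniform within-cluster
null: p = P(Bin(n, 1/w) ≥ k). Benjamini–Hochberg runs across **all**
positions of all clusters (positions without any 5′ end enter as
p = 1), and calls pass at q < 0.001 (`cits_fdr`). The per-position
truncation counts of a cluster sum to n by construction.

## Reproducible peaks

Candidates are cluster pairs overlapping ≥ 1 nt between replicates;
the reported region is their union. Enrichment over the size-matched
input is log2((n1 + n2 + 1)·s / (n_input + 1)) with s the
library-size ratio when known. Reproducibility is
−log10(max(p1, p2)) over the two replicates' Bonferroni-corrected
cluster p-values: a peak is reproducible exactly when it is
independently significant in both replicates. This replaces the full
IDR copula model while preserving its threshold semantics
(−log10 ≥ 2, i.e. both corrected p ≤ 0.01). A rank-consistency
surrogate (agreement of peak-height ranks between replicates) was
evaluated first and rejected: when binding sites have comparable
strength — as in the default simulation — between-replicate height
ranks carry no information (measured Spearman ρ ≈ 0) and the filter
degenerates. Missing input is an error: enrichment over input is not
optional in this design.

## Motif statistics

Foreground windows are peak_center ± 50 (101 nt, a literal reading of
"extended 50 nt on both sides"); background windows are the two
100-nt flanks at ±(450–550), on the peak strand. Windows with > 20 %
repeat-masked bases are discarded; windows running off the chromosome
are dropped with a warning. For each foreground 7-mer,
p = P(Bin(N_fg, f_bg) ≥ n_fg) and Z = (n_fg − N_fg·f_bg) /
√(N_fg·f_bg(1 − f_bg)), with a pseudocount of one background
occurrence for 7-mers absent from the background (prevents infinite
Z on a finite background sample).

Positional profiles count, at each offset o ∈ [−50, 50] from an
anchor (CITS or peak center), the fraction of anchors with a motif
start at o in transcript orientation, divided by the motif's
per-position frequency in the flanking windows. On the − strand the
genomic fetch window is shifted by motif length − 1 so that sense
offsets align exactly with the + strand case.

`seeded_pwm` is an intentionally simplified stand-in for full seeded
crosslink-aware motif discovery: for each seed (top-10 enriched
7-mers), all 7-mer instances within Hamming distance ≤ 1 of the seed
starting within ± 20 nt of a CITS are pooled; the base-frequency
matrix over instances lets degenerate positions emerge from counts,
and the distribution of the CITS offset inside the motif is the
crosslink profile (uniform fallback when no instance covers the
crosslink). The score — mean per-position information content times
the fraction of windows contributing an instance — is this package's
own and is only used to pick the best seed.

## Exon quantification and expression calls

A unique read counts toward every exon it overlaps by ≥ 7 nt
(junction reads once per qualifying exon — deliberate double entry,
tested); reads outside gene spans feed the per-region intergenic
pool; intronic reads count nowhere. Multireads (2–9 alignments;
≥ 10 discarded) are fractionally allocated across their candidate
exons proportionally to unique counts, equal split when all
candidates have zero unique counts; total allocated weight equals the
number of allocated reads.

FPKM = count / (length_kb · mapped_millions), with the sample's
library size = unique reads + multireads. The expression threshold
per sample is the 96th percentile (linear interpolation) of
intergenic-region FPKMs. A unit is expressed in a sample when
FPKM > threshold (strictly); it is retained for analysis when flagged
in ≥ max(1, floor(0.75·n)) replicates of **each** comparison group —
the generalization of the stated 3-of-4 and 2-of-3 rules (ceil would
demand 3-of-3, contradicting the 2-of-3 rule).

Gene counts cascade through constitutivity classes (class 2:
present in > 75 % of the gene's transcripts; class 1: 50–75 %
inclusive; class 0: < 50 %): stage 1 sums expressed class-2 exons;
if the resulting gene FPKM does not exceed the background threshold,
stage 2 adds the remaining class-2 plus expressed class-1 exons, and
stage 3 the remaining class-1 plus expressed class-0 exons; a gene
that still fails detection keeps the full exon sum flagged
not-detected. The detection test at each stage is gene FPKM (stage
counts over stage lengths) > per-sample intergenic threshold — the
cascade's "detection threshold" is not given a formula anywhere, so
this instantiation is the package's own, chosen to satisfy the
stated class-by-class behavior.

## Differential splicing

SI = (exon count / exon length) / (Σ class-2 counts / Σ class-2
lengths) per sample; missing when the constitutive density is zero.
The constitutive denominator uses all class-2 exons of the gene
(annotation-defined constitutivity, not expression-filtered). Group
comparison: log2FC of group mean SI (mutant over wild type) and an
unpaired equal-variance t-test on raw SI values (raw rather than log
because SI is already a ratio centered near 1 for null exons; the
choice is a documented open point). Zero-variance conventions: equal
means → p = 1, unequal means with zero pooled variance → p = 0.
Significance: p ≤ 0.01 and |log2FC| ≥ 1.

Pattern analysis enumerates, from transcript structures: cassette
exons (present in some transcripts, absent from others that retain
both flanks), mutually exclusive pairs (never co-occurring, exactly
one per transcript), and alternative 5′/3′ splice sites (overlapping
exon variants sharing one boundary, donor/acceptor assigned by
strand). Each pattern is quantified through the SI of its
distinguishing exon(s) — cassette patterns one record, the others one
record per alternative exon — so a cassette pattern reproduces the
exon-level result exactly. Nested or more complex patterns are out
of scope.

## Differential expression

Size factors are median-of-ratios: for genes with nonzero counts in
every sample, factor_s = median_g(count_gs / geometric mean_g).
Fold change is computed on normalized group means and reported
signed (ratio when up, −1/ratio when down, so the |FC| ≥ 1.5 filter
is symmetric). The t-test runs on log2(normalized + 1): the log
transform stabilizes variance so the pooled-variance assumption
holds across fold changes; p-values are BH-adjusted across tested
genes and significance needs padj ≤ 0.05 and |FC| ≥ 1.5. Genes enter
the test when cascade-detected in ≥ 3 of 4 replicates per group.

## Integration

The downstream window of an exon is the first 500 nt of downstream
intron in transcript orientation ((end, end+500) on +, (start−500,
start) on −), clipped to the intron; terminal exons have none and
are indirect by default with the reason recorded. A significant exon
is direct when ≥ 1 high-confidence peak overlaps the window by
≥ 1 nt **or** the window holds ≥ `min_motif` = 3 UWAA starts — the
computable form of "densely clustered" motifs; 3 is a configuration
knob, not an inferred ground truth. The direct flag is monotone in
peaks by construction. A truth-evidence mode counts planted motif
sites from the simulation manifest instead of rescanning sequence.

## Synthetic data generator

The generator emulates the observables the analysis consumes, not
sequencing chemistry. Defaults define the reference study
conditions; every stream is seeded (per-stream seeds are CRC32
hashes of (master seed, stream name), so adding samples never
reshuffles existing ones) and outputs are byte-identical across
runs.

* **Genome/annotation** — one chromosome; 40 genes of 5 exons
  (150 nt) and 900-nt introns, alternating strands, arranged in
  paralog pairs with identical layouts (so multimapping reads can be
  mirrored); 75 % of genes carry a middle cassette exon. Cassette
  genes get 4 transcripts making the cassette class 0 (1/4), two
  flanking-internal exons class 1 (3/4), and the terminal exons
  class 2; non-cassette genes get 3 transcripts (two class-1
  internal exons). Background sequence is i.i.d. uniform ACGT.
* **Planted binding** — 300 crosslink sites, 60 % carrying a
  UUWAAAA realization (W drawn per site) with the crosslink at motif
  position 2; 12 direct-target cassette exons receive 3 motif sites
  each in their 500-nt downstream window; 8 indirect-target exons
  get the same inclusion shift but downstream windows scrubbed of
  every UWAA match and no sites. Standalone sites avoid all planted
  windows and keep ≥ 150 nt spacing. Ten 150-nt repeat regions are
  emitted, two of them covering motif-free site windows to exercise
  the 20 % repeat filter.
* **CLIP tags** — per IP replicate: background tags uniform over
  gene spans at 0.02 tags/nt, plus Poisson(50) burst tags per site
  whose 5′ ends sit exactly at the crosslink with probability 0.7
  (else uniform within ±10 nt sense offset); the input track is
  uniform over the genome. Tag length 30 nt.
* **RNA-seq** — per gene and sample, fragments ~ NB(200·n_exons,
  dispersion 0.05) (variance = μ + μ²·disp); planted
  differentially expressed genes (3 non-cassette genes at folds
  1.8/3.0/4.7) scale μ in the mutant group. Each fragment picks the
  cassette-inclusion isoform with ψ: null cassettes ψ = 0.5 in both
  groups; planted exons ψ_wt = 0.2 and ψ_mut = 0.45 (Δψ = +0.25,
  increased inclusion in the mutant — the repressor-loss direction).
  ψ_wt = 0.2 places the planted effect at an SI ratio of 2.25
  (log2 ≈ 1.17), the regime the |log2FC| ≥ 1 threshold targets; at
  ψ_wt = 0.5 the same Δψ gives a ratio of 1.5, which that filter is
  designed to reject. Reads (75 nt) are uniform along the chosen
  transcript and emitted as genomic BED12 blocks including junction
  reads; 2 % of reads gain a mirrored second alignment in the
  paralog partner, and 2 % extra noise reads fall uniformly over the
  genome to populate the intergenic background.
* **Gene-count calibration matrix** — for expression-analysis
  calibration at scale (1000 genes), counts are drawn directly at
  gene level with per-gene means 0.25–4× of 500 and dispersion 0.01,
  reflecting the low replicate-to-replicate variance of good
  affinity-purified bulk libraries; read-level simulation keeps
  dispersion 0.05.

What the generator does **not** model — and hence what passing tests
do not establish about real data: sequencing errors, fragment-length
and positional coverage biases, UMI chemistry, non-uniform genomic
background (GC, mappability), overlapping genes, transcript-level
expression differences beyond one cassette per gene, and annotation
incompleteness. Recovery rates on this generator are upper bounds on
real-data performance; the calibration checks (null cluster counts,
null 7-mer p-value fraction, null differential calls) are the more
transferable results.

## Validation scales and numerical choices

The default validation run uses 40 genes / 200 exons / ~300 clusters
/ 4 vs 4 replicates, chosen so the full pipeline completes in tens
of seconds while leaving every statistic in its asymptotic regime;
the expression calibration uses a 1000-gene matrix. Percentiles use
linear interpolation between order statistics. BH uses the standard
step-up; Bonferroni caps at 1. The t statistic uses the pooled
(equal-variance) form throughout, matching the stated test; Welch is
a one-line change but is not the default. Probabilities inside
−log10 are floored at 1e-300. Ties in peak-center argmax take the
leftmost maximum.

## Known limitations

* Cluster p-values are computed gene-locally; transcriptome-wide
  nulls (as some published pipelines use) would be less conservative.
* The seeded PWM refinement is a simplified surrogate; its score has
  no probabilistic interpretation and should only be used to rank
  seeds.
* The pattern catalog covers the four canonical kinds; intron
  retention and nested events are not enumerated.
* The equal-variance t-test on raw SI is approximate for ratio
  statistics; its realized type-I error at nominal 0.01 sits within
  [0.005, 0.02] under the null simulation, and the |log2FC| filter
  dominates specificity in practice.
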