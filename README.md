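# clipsplice

Neuronal RNA-binding proteins such as the KH-domain protein SLM2
(KHDRBS3) shape synapse properties by repressing inclusion of specific
alternative exons. Establishing that a protein *directly* drives an
exon's regulation takes three independent genome-wide measurements tied
together: where the protein binds (eCLIP), what sequence it recognizes
(motif enrichment at crosslink sites), and which exons change when the
protein is removed (exon-level differential splicing in conditional
knockouts). `clipsplice` implements that integrated analysis as a
tested, reusable pipeline, together with a seeded synthetic-data
generator so every stage can be validated end to end against planted
ground truth — no sequencing data or external databases required.

It is aimed at computational biologists who want a transparent,
self-contained re-implementation of this class of CLIP + RNA-seq
integration analysis, with every statistical rule explicit and unit
tested.

## What it computes

**CLIP tag clusters.** Deduplicated CLIP tags (BED6; the 5′ end marks
the reverse-transcriptase truncation site) are merged into candidate
clusters. With λ_g = (gene tag count)/(gene length), a cluster of n
tags and width w has p = P(Pois(λ_g·w) ≥ n), Bonferroni-corrected over
all candidates; clusters with corrected p < 0.05 are kept.

**Crosslink-induced truncation sites (CITS).** Within a cluster of n
tags and width w, a position with k coincident 5′ ends has
p = P(Bin(n, 1/w) ≥ k); calls are kept at Benjamini–Hochberg FDR
< 0.001.

**High-confidence peaks.** Clusters overlapping between replicates are
scored against the size-matched input: log2FC of pooled IP density over
input density (pseudocount 1 per region) and a reproducibility score
−log10(max of the two replicates' corrected cluster p-values); peaks
need log2FC ≥ 2 and reproducibility ≥ 2.

**Motif enrichment.** 7-mers are counted in repeat-filtered 101-nt
windows around peak centers (peak height ≥ 10) versus 100-nt flanks at
±(450–550); each 7-mer gets a binomial p and Z score
(fg − N·f_bg)/√(N·f_bg(1−f_bg)). Positional profiles report the
frequency of a degenerate motif (UWAA, W = U/A) starting at each offset
from the CITS, normalized by its flank frequency. A simplified seeded
refinement turns the top 7-mers into a PWM with a per-position
crosslink profile.

**Splicing index (SI).** Exon-level counts follow the two-stage scheme:
unique reads count toward every exon they overlap by ≥ 7 nt (junction
reads once per flanking exon), then multimapping reads are fractionally
allocated by unique-count proportions. Exons and genes count as
expressed when FPKM exceeds the 96th percentile of intergenic
background. SI = (exon read density)/(constitutive-exon read density of
the same gene), with constitutive = exons in > 75 % of the gene's
transcripts. Differential exons need p ≤ 0.01 (unpaired t) and
|log2FC| ≥ 1; gene-level expression uses median-of-ratios
normalization, a t-test on log2 values, BH adjustment, and
|FC| ≥ 1.5 at padj ≤ 0.05.

**Integration.** A significantly deregulated exon is a **direct**
target when binding evidence lies within the 500-nt downstream-intron
window (strand-aware, intron-clipped): ≥ 1 high-confidence peak or ≥ 3
UWAA motif starts; otherwise it is indirect.

## Worked example

```python
from clipsplice.pipeline import RunConfig, full_run

report = full_run(RunConfig(seed=1), "run1")
```

On the default simulation (40 genes, 200 exons, 300 planted binding
sites of which 60 % carry a UUWAAAA realization, 4 vs 4 replicates,
Δψ = +0.25 on 20 planted exons) this prints into `run1/report.json`:

```
clusters: 299
CITS: 300
high-confidence peaks: 201
top 7-mers: UUAAAAA, UUUAAAA, AAAAACC
PWM consensus: UUWAAAA
UWAA profile argmax offset: -1
significant exons: 19
CITS recovery: {'sensitivity': 1.0, 'fdp': 0.0, 'n_calls': 300}
exon recovery: {'sensitivity': 0.95, 'false_positives': 0,
                'n_null': 180, 'direction_agreement': 1.0}
direct/indirect accuracy (called peaks): 1.0
```

Reading this: the caller found essentially every planted cluster and
crosslink site with no false truncation calls; the top enriched 7-mers
are realizations of the planted degenerate motif and the recovered PWM
consensus is UUWAAAA itself; the UWAA tetramer peaks one base upstream
of the crosslink, exactly where the planted geometry puts it; 19 of the
20 planted inclusion shifts are recovered with zero false positives
among 180 null exons, all in the increased-inclusion direction expected
when a splicing repressor is removed; and every recovered exon is
correctly labelled direct (motif/binding in the downstream window)
versus indirect.

The same stages are exposed as a CLI:

```bash
clipsplice simulate  --seed 1 --out sim/
clipsplice clip-call --tags sim/tags_ip_rep1.bed --tags sim/tags_ip_rep2.bed \
                     --input sim/tags_input.bed --gtf sim/annotation.gtf --out out/
clipsplice motif     --clusters out/clusters.tsv --cits out/cits.tsv \
                     --genome sim/genome.fa --mask sim/repeats.bed --out out/
clipsplice splice    --reads sim/ --gtf sim/annotation.gtf --samples sim/samples.tsv --out out/
clipsplice dge       --reads sim/ --gtf sim/annotation.gtf --samples sim/samples.tsv --out out/
clipsplice integrate --diff out/si_differential.tsv --peaks out/peaks.tsv \
                     --genome sim/genome.fa --gtf sim/annotation.gtf --out out/
clipsplice full-run  --seed 1 --out run1/
```

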