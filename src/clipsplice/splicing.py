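"""Exon-level quantification, splicing-index differential splicing, and
differential gene expression.

Quantification follows a two-stage scheme: unique reads are counted per
exon (a read counts toward every exon it overlaps by at least
``MIN_OVERLAP_NT`` nucleotides, so a junction read counts once toward
each flanking exon), then multimapping reads are fractionally allocated
to their candidate exons in proportion to the unique counts.  Exon and
gene expression calls compare FPKM with the 96th percentile of the
intergenic-background FPKM distribution.  The splicing index (SI) of an
exon is its read density divided by the read density of the gene's
constitutive (class-2) exons; group differences use an unpaired
equal-variance t-test on per-sample SI values with significance at
p <= 0.01 and |log2FC| >= 1.  Gene-level counts are summed through the
constitutivity-class cascade, and differential expression uses
median-of-ratios normalization, a t-test, and Benjamini-Hochberg
adjustment with significance at padj <= 0.05 and |FC| >= 1.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import (
    GenomeAnnotation,
    GeneModel,
    classify_constitutivity,
    intergenic_regions,
)
from .clip import bh_adjust
from .io import ReadRecord

log = logging.getLogger(__name__)

MIN_OVERLAP_NT = 7
MAX_ALIGNMENTS = 9  # reads with 10 or more alignments are discarded


def exon_table(ann: GenomeAnnotation) -> pd.DataFrame:
    """Per-exon table: coordinates, length, constitutivity fraction/class."""
    rows = []
    for g in ann.genes:
        classes = classify_constitutivity(g)
        for i, (s, e) in enumerate(g.exons):
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "exon_index": i,
                    "chrom": g.chrom,
                    "start": s,
                    "end": e,
                    "strand": g.strand,
                    "length": e - s,
                    "fraction": classes[i].fraction,
                    "cls": classes[i].cls,
                }
            )
    df = pd.DataFrame(rows)
    return df.set_index(["gene_id", "exon_index"])


class _ExonIndex:
    """Interval lookup from genomic blocks to exons and gene spans."""

    def __init__(self, ann: GenomeAnnotation):
        self.exon_trees: dict[str, IntervalTree] = {}
        self.gene_trees: dict[str, IntervalTree] = {}
        for g in ann.genes:
            gt = self.gene_trees.setdefault(g.chrom, IntervalTree())
            gt.addi(g.span.start, g.span.end, g.gene_id)
            et = self.exon_trees.setdefault(g.chrom, IntervalTree())
            for i, (s, e) in enumerate(g.exons):
                et.addi(s, e, (g.gene_id, i))
        self.intergenic = intergenic_regions(ann)
        self.inter_trees: dict[str, IntervalTree] = {}
        for idx, r in enumerate(self.intergenic):
            self.inter_trees.setdefault(r.chrom, IntervalTree()).addi(
                r.start, r.end, idx
            )

    def exon_overlaps(self, read: ReadRecord) -> dict[tuple[str, int], int]:
        """Total overlap in nt of a read's blocks with each exon."""
        out: dict[tuple[str, int], int] = {}
        for b in read.blocks:
            tree = self.exon_trees.get(b.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(b.start, b.end):
                nt = min(b.end, iv.end) - max(b.start, iv.begin)
                out[iv.data] = out.get(iv.data, 0) + nt
        return out

    def in_gene(self, read: ReadRecord) -> bool:
        for b in read.blocks:
            tree = self.gene_trees.get(b.chrom)
            if tree is not None and tree.overlaps(b.start, b.end):
                return True
        return False

    def intergenic_region_of(self, read: ReadRecord) -> int | None:
        b = read.blocks[0]
        tree = self.inter_trees.get(b.chrom)
        if tree is None:
            return None
        hits = tree[b.start]
        return next(iter(hits)).data if hits else None


def assign_reads_to_exons(
    reads: list[ReadRecord],
    ann: GenomeAnnotation,
    index: _ExonIndex | None = None,
    min_overlap: int = MIN_OVERLAP_NT,
):
    """Count unique reads per exon; junction reads count toward every
    exon they overlap by >= ``min_overlap`` nt.

    Returns ``(exon_counts, intergenic_counts, n_reads)`` where
    ``exon_counts`` maps (gene_id, exon_index) to read counts and
    ``intergenic_counts`` maps intergenic-region index to counts of
    reads falling entirely outside gene spans.
    """
    index = index or _ExonIndex(ann)
    exon_counts: dict[tuple[str, int], int] = {}
    inter_counts: dict[int, int] = {}
    for r in reads:
        if r.n_alignments != 1:
            raise ValueError("assign_reads_to_exons expects unique reads")
        hits = index.exon_overlaps(r)
        assigned = False
        for exon_ref, nt in hits.items():
            if nt >= min_overlap:
                exon_counts[exon_ref] = exon_counts.get(exon_ref, 0) + 1
                assigned = True
        if not assigned and not index.in_gene(r):
            ridx = index.intergenic_region_of(r)
            if ridx is not None:
                inter_counts[ridx] = inter_counts.get(ridx, 0) + 1
    return exon_counts, inter_counts, len(reads)


def multiread_candidates(
    alignments: list[ReadRecord],
    index: _ExonIndex,
    min_overlap: int = MIN_OVERLAP_NT,
) -> list[tuple[str, int]]:
    """Candidate exons of one multiread: exons overlapped >= min_overlap
    nt by any of its alignments."""
    cands: set[tuple[str, int]] = set()
    for a in alignments:
        for exon_ref, nt in index.exon_overlaps(a).items():
            if nt >= min_overlap:
                cands.add(exon_ref)
    return sorted(cands)


def allocate_multimappers(
    candidates: list[list[tuple[str, int]]],
    unique_counts: dict[tuple[str, int], float],
) -> dict[tuple[str, int], float]:
    """Fractionally allocate multireads to candidate exons.

    Each read contributes total weight 1, split across its candidate
    exons in proportion to their unique counts; candidates that all
    have zero unique counts share the weight equally.  Reads without
    candidates contribute nothing.
    """
    alloc: dict[tuple[str, int], float] = {}
    for cands in candidates:
        if not cands:
            continue
        w = np.array([unique_counts.get(c, 0) for c in cands], dtype=float)
        if w.sum() == 0:
            w[:] = 1.0
        w /= w.sum()
        for c, wi in zip(cands, w):
            alloc[c] = alloc.get(c, 0.0) + float(wi)
    return alloc


def count_sample(
    reads: list[ReadRecord],
    ann: GenomeAnnotation,
    index: _ExonIndex | None = None,
):
    """Full two-stage counting of one sample's reads.

    Splits alignments into unique reads and multireads (grouped by
    name; reads with more than ``MAX_ALIGNMENTS`` alignments are
    discarded), counts unique reads, then allocates multireads.
    Returns ``(total_counts, unique_counts, intergenic_counts,
    library_size)``.
    """
    index = index or _ExonIndex(ann)
    unique = [r for r in reads if r.n_alignments == 1]
    multis: dict[str, list[ReadRecord]] = {}
    n_discarded = 0
    for r in reads:
        if r.n_alignments > 1:
            if r.n_alignments > MAX_ALIGNMENTS:
                n_discarded += 1
                continue
            multis.setdefault(r.name, []).append(r)
    if n_discarded:
        log.info("discarded %d alignments of reads with >%d alignments",
                 n_discarded, MAX_ALIGNMENTS)
    uniq_counts, inter_counts, _ = assign_reads_to_exons(unique, ann, index)
    cands = [
        multiread_candidates(aligns, index) for aligns in multis.values()
    ]
    alloc = allocate_multimappers(cands, uniq_counts)
    total = {k: float(v) for k, v in uniq_counts.items()}
    for k, v in alloc.items():
        total[k] = total.get(k, 0.0) + v
    library_size = len(unique) + len(multis)
    return total, uniq_counts, inter_counts, library_size


def count_table(
    reads_by_sample: dict[str, list[ReadRecord]],
    ann: GenomeAnnotation,
):
    """Exon count matrix over samples plus intergenic counts and library
    sizes."""
    index = _ExonIndex(ann)
    exons = exon_table(ann)
    counts = pd.DataFrame(0.0, index=exons.index,
                          columns=list(reads_by_sample))
    inter = pd.DataFrame(
        0.0, index=range(len(index.intergenic)), columns=list(reads_by_sample)
    )
    libs = pd.Series(0, index=list(reads_by_sample), dtype=int)
    for sample, reads in reads_by_sample.items():
        total, _uniq, inter_c, lib = count_sample(reads, ann, index)
        if total:
            s = pd.Series(total)
            s.index = pd.MultiIndex.from_tuples(
                s.index, names=["gene_id", "exon_index"]
            )
            counts[sample] = s.reindex(counts.index).fillna(0.0)
        for ridx, c in inter_c.items():
            inter.loc[ridx, sample] = c
        libs[sample] = lib
    return counts, inter, libs, index


def compute_fpkm(
    counts, lengths, library_sizes
) -> pd.DataFrame:
    """FPKM = count / (length in kb * mapped reads in millions)."""
    lengths = pd.Series(lengths)
    if (lengths <= 0).any():
        raise ValueError("zero-length unit in FPKM computation")
    library_sizes = pd.Series(library_sizes)
    if (library_sizes <= 0).any():
        raise ValueError("library size must be positive")
    counts = pd.DataFrame(counts)
    denom = np.outer(lengths / 1e3, library_sizes / 1e6)
    return pd.DataFrame(
        counts.values / denom, index=counts.index, columns=counts.columns
    )


def background_threshold(intergenic_fpkms, q: float = 96.0) -> float:
    """``q``-th percentile (linear interpolation) of intergenic FPKM
    values; the expression cutoff defaults to the 96th percentile."""
    v = np.asarray(intergenic_fpkms, dtype=float)
    if v.size == 0:
        raise ValueError("no intergenic FPKM values")
    if v.size < 25:
        log.warning(
            "only %d intergenic regions; background threshold is unstable",
            v.size,
        )
    return float(np.percentile(v, q))


def expression_flags(
    fpkm: pd.DataFrame,
    thresholds: pd.Series,
    groups: dict[str, str],
):
    """Per-sample expression flags and per-unit retention.

    A sample's flag is ``fpkm > threshold`` (strict).  A unit is
    retained when, within every comparison group, it is flagged in at
    least ``max(1, floor(0.75 * n_group))`` replicates — the
    generalization of the stated 3-of-4 and 2-of-3 rules.
    """
    thresholds = pd.Series(thresholds).reindex(fpkm.columns)
    flags = fpkm.gt(thresholds, axis=1)
    retained = pd.Series(True, index=fpkm.index)
    for grp in sorted(set(groups.values())):
        samples = [s for s in fpkm.columns if groups.get(s) == grp]
        if not samples:
            continue
        need = max(1, math.floor(0.75 * len(samples)))
        retained &= flags[samples].sum(axis=1) >= need
    return flags, retained


def gene_counts_cascade(
    exon_counts: pd.DataFrame,
    exons: pd.DataFrame,
    flags: pd.DataFrame,
    thresholds: pd.Series,
    library_sizes: pd.Series,
):
    """Gene-level counts through the constitutivity cascade.

    Stage 1 sums expressed class-2 exons; if the resulting gene FPKM
    does not exceed the intergenic background threshold, stage 2 adds
    the remaining class-2 and the expressed class-1 exons, and stage 3
    the remaining class-1 and expressed class-0 exons.  A gene that
    still fails detection is flagged not-detected and keeps the full
    exon sum.  Returns ``(gene_counts, detected, classes_used)``, all
    per gene x sample.
    """
    thresholds = pd.Series(thresholds).reindex(exon_counts.columns)
    library_sizes = pd.Series(library_sizes).reindex(exon_counts.columns)
    genes = exons.index.get_level_values("gene_id").unique()
    gene_counts = pd.DataFrame(
        0.0, index=genes, columns=exon_counts.columns
    )
    detected = pd.DataFrame(False, index=genes, columns=exon_counts.columns)
    classes_used = pd.DataFrame(
        "", index=genes, columns=exon_counts.columns, dtype=object
    )
    for gene_id, sub in exons.groupby(level="gene_id", sort=False):
        if sub.empty:
            raise ValueError(f"{gene_id}: gene with no exons")
        c = exon_counts.loc[sub.index]
        f = flags.loc[sub.index]
        lengths = sub["length"]
        cls = sub["cls"]
        for sample in exon_counts.columns:
            thr = thresholds[sample]
            lib_m = library_sizes[sample] / 1e6
            stages = [
                ((cls == 2) & f[sample], "2"),
                ((cls == 2) | ((cls == 1) & f[sample]), "2+1"),
                (
                    (cls >= 1) | ((cls == 0) & f[sample]),
                    "2+1+0",
                ),
            ]
            done = False
            for mask, label in stages:
                total = c.loc[mask.values, sample].sum()
                tot_len = lengths[mask.values].sum()
                if tot_len > 0:
                    fpkm = total / (tot_len / 1e3) / lib_m
                    if fpkm > thr:
                        gene_counts.loc[gene_id, sample] = total
                        detected.loc[gene_id, sample] = True
                        classes_used.loc[gene_id, sample] = label
                        done = True
                        break
            if not done:
                gene_counts.loc[gene_id, sample] = c[sample].sum()
                classes_used.loc[gene_id, sample] = "all(not detected)"
    return gene_counts, detected, classes_used


def splicing_index(
    exon_counts: pd.DataFrame,
    exons: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample SI: exon read density over the gene's constitutive
    (class-2) exon density; NaN where the constitutive density is 0 or
    the gene has no class-2 exon."""
    si = pd.DataFrame(
        np.nan, index=exon_counts.index, columns=exon_counts.columns
    )
    lengths = exons["length"]
    is_const = exons["cls"] == 2
    for gene_id, sub in exons.groupby(level="gene_id", sort=False):
        const_idx = sub.index[is_const.loc[sub.index]]
        if len(const_idx) == 0:
            continue
        const_counts = exon_counts.loc[const_idx].sum(axis=0)
        const_len = lengths.loc[const_idx].sum()
        const_density = const_counts / const_len
        dens = exon_counts.loc[sub.index].div(
            lengths.loc[sub.index], axis=0
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = dens.values / const_density.values[None, :]
        vals[:, const_density.values <= 0] = np.nan
        si.loc[sub.index] = vals
    return si


def _ttest_rows(a: np.ndarray, b: np.ndarray):
    """Row-wise unpaired equal-variance t-test with zero-variance
    conventions: equal means -> p = 1; unequal means with zero pooled
    variance -> p = 0."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / se
    p = 2 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    zero_var = se == 0
    p[zero_var & (m1 == m2)] = 1.0
    p[zero_var & (m1 != m2)] = 0.0
    return t, p


def differential_splicing(
    si: pd.DataFrame,
    groups: dict[str, str],
    wt_group: str,
    mut_group: str,
    *,
    p_max: float = 0.01,
    lfc_min: float = 1.0,
    min_reps: int = 2,
) -> pd.DataFrame:
    """Group comparison of per-sample SI values.

    log2FC = log2(mean SI mutant / mean SI wild type); p from an
    unpaired equal-variance t-test on raw SI values; significant when
    p <= ``p_max`` and |log2FC| >= ``lfc_min``.  Exons with fewer than
    ``min_reps`` non-missing replicates in either group are skipped
    (reason recorded).
    """
    wt_cols = [s for s in si.columns if groups.get(s) == wt_group]
    mut_cols = [s for s in si.columns if groups.get(s) == mut_group]
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise ValueError("need >=2 replicates per group")
    wt = si[wt_cols].values
    mut = si[mut_cols].values
    ok = (
        (~np.isnan(wt)).sum(axis=1) >= min_reps
    ) & ((~np.isnan(mut)).sum(axis=1) >= min_reps)
    # t-test requires complete rows; drop rows with any missing value
    complete = ok & ~np.isnan(wt).any(axis=1) & ~np.isnan(mut).any(axis=1)
    out = pd.DataFrame(index=si.index)
    with np.errstate(invalid="ignore"):
        out["mean_wt"] = np.where(
            np.isnan(wt).all(axis=1), np.nan,
            np.nansum(wt, axis=1) / np.maximum((~np.isnan(wt)).sum(axis=1), 1),
        )
        out["mean_mut"] = np.where(
            np.isnan(mut).all(axis=1), np.nan,
            np.nansum(mut, axis=1)
            / np.maximum((~np.isnan(mut)).sum(axis=1), 1),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2fc"] = np.log2(out["mean_mut"] / out["mean_wt"])
    out["p"] = np.nan
    if complete.any():
        _t, p = _ttest_rows(wt[complete], mut[complete])
        out.loc[complete, "p"] = p
    out["significant"] = (
        (out["p"] <= p_max) & (out["log2fc"].abs() >= lfc_min)
    ).fillna(False)
    out["skipped"] = ~complete
    out.loc[~ok, "skipped_reason"] = "insufficient non-missing replicates"
    return out


@dataclass(frozen=True)
class SplicingPattern:
    gene_id: str
    pattern_id: str
    kind: str  # cassette, mutually_exclusive, alt5, alt3
    exons: tuple[int, ...]


def enumerate_patterns(gene: GeneModel) -> list[SplicingPattern]:
    """Enumerate cassette, mutually exclusive, and alt-5'/3' splice-site
    patterns from the gene's transcript structures.  Complex nested
    patterns are not enumerated."""
    pats: list[SplicingPattern] = []
    n = len(gene.exons)
    txs = gene.transcripts
    frac = [sum(1 for t in txs if i in t) / len(txs) for i in range(n)]

    def overlapping(i, j):
        (s1, e1), (s2, e2) = gene.exons[i], gene.exons[j]
        return s1 < e2 and s2 < e1

    for i in range(n):
        if not (0 < frac[i] < 1):
            continue
        if any(overlapping(i, j) for j in range(n) if j != i):
            continue
        skipping = [t for t in txs if i not in t]
        has_flanks = any(
            any(j < i for j in t) and any(j > i for j in t) for t in skipping
        )
        if has_flanks:
            pats.append(
                SplicingPattern(
                    gene.gene_id, f"{gene.gene_id}:cassette:{i}",
                    "cassette", (i,),
                )
            )
    for i in range(n):
        for j in range(i + 1, n):
            if frac[i] >= 1 or frac[j] >= 1 or overlapping(i, j):
                continue
            if all((i in t) != (j in t) for t in txs):
                pats.append(
                    SplicingPattern(
                        gene.gene_id,
                        f"{gene.gene_id}:mutually_exclusive:{i}-{j}",
                        "mutually_exclusive", (i, j),
                    )
                )
    for i in range(n):
        for j in range(i + 1, n):
            if not overlapping(i, j):
                continue
            (s1, e1), (s2, e2) = gene.exons[i], gene.exons[j]
            if s1 == s2 and e1 != e2:
                kind = "alt5" if gene.strand == "+" else "alt3"
            elif e1 == e2 and s1 != s2:
                kind = "alt3" if gene.strand == "+" else "alt5"
            else:
                continue
            pats.append(
                SplicingPattern(
                    gene.gene_id, f"{gene.gene_id}:{kind}:{i}-{j}", kind,
                    (i, j),
                )
            )
    return pats


def pattern_si(
    exon_counts: pd.DataFrame,
    exons: pd.DataFrame,
    ann: GenomeAnnotation,
    groups: dict[str, str],
    wt_group: str,
    mut_group: str,
    *,
    p_max: float = 0.01,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Pattern-level differential SI.

    For each annotated pattern the SI of each pattern-specific exon
    (the exon bases plus the junction reads already assigned to it)
    is compared between groups as in :func:`differential_splicing`.
    A cassette pattern yields one record; mutually exclusive and
    alt-splice-site patterns yield one record per alternative exon.
    """
    si = splicing_index(exon_counts, exons)
    rows = []
    for gene in ann.genes:
        for pat in enumerate_patterns(gene):
            for i in pat.exons:
                rows.append((pat.gene_id, pat.pattern_id, pat.kind, i))
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "pattern_id", "pattern_kind", "exon_index",
                     "mean_wt", "mean_mut", "log2fc", "p", "significant"]
        )
    idx = pd.MultiIndex.from_tuples(
        [(g, i) for g, _, _, i in rows], names=["gene_id", "exon_index"]
    )
    sub_si = si.loc[idx]
    diff = differential_splicing(
        sub_si, groups, wt_group, mut_group, p_max=p_max, lfc_min=lfc_min
    )
    out = pd.DataFrame(
        {
            "gene_id": [g for g, _, _, _ in rows],
            "pattern_id": [p for _, p, _, _ in rows],
            "pattern_kind": [k for _, _, k, _ in rows],
            "exon_index": [i for _, _, _, i in rows],
        }
    )
    for col in ("mean_wt", "mean_mut", "log2fc", "p", "significant"):
        out[col] = diff[col].values
    return out


def size_factors(gene_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with nonzero counts in every sample, the factor of a
    sample is the median of count / geometric-mean-across-samples.
    """
    counts = gene_counts.loc[(gene_counts > 0).all(axis=1)]
    if counts.empty:
        raise ValueError("no gene has nonzero counts in all samples")
    log_geo = np.log(counts).mean(axis=1)
    ratios = np.exp(np.log(counts).sub(log_geo, axis=0))
    return ratios.median(axis=0)


def differential_expression(
    norm_counts: pd.DataFrame,
    groups: dict[str, str],
    wt_group: str,
    mut_group: str,
    *,
    padj_max: float = 0.05,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """Differential expression on normalized counts.

    Fold change is signed: the mutant/wild-type ratio when expression
    increases, minus its reciprocal when it decreases (so "FC >= +/-1.5"
    reads |fc| >= 1.5).  p from an unpaired equal-variance t-test on
    log2(normalized count + 1) — the log transform stabilizes the
    variance so the pooled-variance assumption holds across fold
    changes — Benjamini-Hochberg adjusted across tested genes.
    """
    wt_cols = [s for s in norm_counts.columns if groups.get(s) == wt_group]
    mut_cols = [s for s in norm_counts.columns if groups.get(s) == mut_group]
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise ValueError("need >=2 replicates per group")
    wt = norm_counts[wt_cols].values.astype(float)
    mut = norm_counts[mut_cols].values.astype(float)
    m_wt, m_mut = wt.mean(axis=1), mut.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m_mut / m_wt
        fc = np.where(ratio >= 1, ratio, -1.0 / ratio)
    _t, p = _ttest_rows(np.log2(wt + 1), np.log2(mut + 1))
    padj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "mean_wt": m_wt,
            "mean_mut": m_mut,
            "fc": fc,
            "p": p,
            "padj": padj,
        },
        index=norm_counts.index,
    )
    out["significant"] = (out["padj"] <= padj_max) & (
        np.abs(out["fc"]) >= fc_min
    )
    return out
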