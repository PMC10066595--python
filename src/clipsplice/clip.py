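"""Tag-cluster, truncation-site (CITS), and reproducible peak calling.

Clusters are maximal runs of overlapping CLIP tags.  Cluster
significance is assessed against a gene-local Poisson null: with
``lambda_gene`` = gene tag count / gene length, the expected tag count
in a candidate of width w is ``lambda_gene * w`` and the p-value is the
Poisson upper tail P(X >= n_tags), Bonferroni-corrected over the number
of candidate clusters genome-wide.  Tags outside annotated genes share
an intergenic background rate.

Within a significant cluster, a crosslink-induced truncation site is a
position where tag 5' ends pile up beyond the within-cluster uniform
binomial null: p = P(X >= k | n = cluster tags, p0 = 1/width), with
Benjamini-Hochberg control across all positions of all clusters.

Replicate reproducibility uses a dual-significance surrogate in place
of the full IDR copula model: every candidate peak (a >=1 nt overlap of
replicate clusters) gets ``reproducibility = -log10(max(p1, p2))``
where p1, p2 are the overlapping clusters' Bonferroni-corrected
p-values in the two replicates — a peak is reproducible exactly when it
is independently significant in both replicates, which is what the IDR
filter retains in practice.  Peaks are kept when both
``log2fc_vs_input >= 2`` and ``reproducibility >= 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotation import GenomeAnnotation, Region, intergenic_regions
from .io import ClipTag

P_FLOOR = 1e-300  # floor on corrected p-values inside -log10


@dataclass
class TagCluster:
    region: Region
    n_tags: int
    peak_height: int
    peak_center: int
    p_raw: float
    p_bonferroni: float
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.n_tags >= self.peak_height >= 1):
            raise ValueError("need n_tags >= peak_height >= 1")
        if not (self.region.start <= self.peak_center < self.region.end):
            raise ValueError("peak_center outside cluster region")


@dataclass
class CitsCall:
    chrom: str
    strand: str
    position: int
    k_trunc: int
    n_tags: int
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.k_trunc > self.n_tags:
            raise ValueError("k_trunc cannot exceed n_tags")


@dataclass
class HighConfidencePeak:
    region: Region
    log2fc_vs_input: float
    reproducibility: float
    gene_id: str | None = None


def _tag_arrays(tags: list[ClipTag]):
    """Group tags by (chrom, strand) into sorted (start, end, five') arrays."""
    groups: dict[tuple[str, str], list[ClipTag]] = {}
    for t in tags:
        groups.setdefault((t.chrom, t.strand), []).append(t)
    out = {}
    for key, ts in groups.items():
        starts = np.array([t.start for t in ts])
        order = np.argsort(starts, kind="stable")
        out[key] = (
            starts[order],
            np.array([t.end for t in ts])[order],
            np.array([t.five_prime for t in ts])[order],
        )
    return out


def _candidate_clusters(tags: list[ClipTag]):
    """Maximal runs of overlapping tags per (chrom, strand).

    Yields (chrom, strand, start, end, n_tags, peak_height, peak_center,
    five_prime_positions).
    """
    for (chrom, strand), (starts, ends, fives) in _tag_arrays(tags).items():
        i = 0
        n = len(starts)
        while i < n:
            j = i + 1
            cur_end = ends[i]
            while j < n and starts[j] < cur_end:
                cur_end = max(cur_end, ends[j])
                j += 1
            s, e = int(starts[i]), int(cur_end)
            cov = np.zeros(e - s + 1, dtype=np.int32)
            np.add.at(cov, starts[i:j] - s, 1)
            np.add.at(cov, ends[i:j] - s, -1)
            cov = np.cumsum(cov[:-1])
            ph = int(cov.max())
            center = s + int(np.argmax(cov))
            yield chrom, strand, s, e, j - i, ph, center, fives[i:j]
            i = j


def _gene_rates(tags: list[ClipTag], ann: GenomeAnnotation):
    """Per-gene tag rate (tags/nt) plus the intergenic background rate.

    A tag is assigned to the first same-strand gene whose span contains
    its 5' end; unassigned tags feed the intergenic rate.
    """
    by_chrom: dict[str, list] = {}
    for g in ann.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.span.start)

    counts: dict[str, int] = {g.gene_id: 0 for g in ann.genes}
    n_unassigned = 0
    lookup = {}
    for chrom, genes in by_chrom.items():
        lookup[chrom] = (
            np.array([g.span.start for g in genes]),
            np.array([g.span.end for g in genes]),
            genes,
        )
    for t in tags:
        gene = _locate_gene(lookup, t.chrom, t.five_prime, t.strand)
        if gene is None:
            n_unassigned += 1
        else:
            counts[gene.gene_id] += 1
    rates = {
        g.gene_id: counts[g.gene_id] / g.length for g in ann.genes
    }
    inter_len = sum(r.width for r in intergenic_regions(ann))
    bg_rate = n_unassigned / inter_len if inter_len > 0 else 0.0
    return rates, bg_rate, lookup


def _locate_gene(lookup, chrom, pos, strand):
    if chrom not in lookup:
        return None
    starts, ends, genes = lookup[chrom]
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    # walk left over genes that start before pos; spans may nest slightly
    while i >= 0:
        if ends[i] > pos and genes[i].strand == strand:
            return genes[i]
        if ends[i] > pos:
            i -= 1
            continue
        break
    return None


def _best_overlap_gene(lookup, chrom, start, end, strand):
    """Same-strand gene with the largest overlap of [start, end)."""
    if chrom not in lookup:
        return None
    starts, ends, genes = lookup[chrom]
    best, best_nt = None, 0
    for g, gs, ge in zip(genes, starts, ends):
        nt = min(end, ge) - max(start, gs)
        if nt > best_nt and g.strand == strand:
            best, best_nt = g, nt
    return best


def call_clusters(
    tags: list[ClipTag],
    ann: GenomeAnnotation,
    alpha: float = 0.05,
    keep_all: bool = False,
) -> list[TagCluster]:
    """Call significant tag clusters (Bonferroni-corrected Poisson test).

    ``keep_all`` returns every candidate (for null-calibration studies);
    by default only clusters with ``p_bonferroni < alpha`` are returned.
    """
    if not tags:
        return []
    candidates = list(_candidate_clusters(tags))
    m = len(candidates)
    rates, bg_rate, lookup = _gene_rates(tags, ann)

    out = []
    for chrom, strand, s, e, n, ph, center, _fives in candidates:
        gene = _locate_gene(lookup, chrom, center, strand)
        if gene is None:
            # cluster straddling a gene boundary: use the overlapped gene
            gene = _best_overlap_gene(lookup, chrom, s, e, strand)
        rate = rates[gene.gene_id] if gene is not None else bg_rate
        mean = rate * (e - s)
        p_raw = float(stats.poisson.sf(n - 1, mean)) if mean > 0 else (
            0.0 if n > 0 else 1.0
        )
        p_bonf = min(1.0, p_raw * m)
        if keep_all or p_bonf < alpha:
            out.append(
                TagCluster(
                    Region(chrom, s, e, strand), n, ph, center, p_raw, p_bonf,
                    gene.gene_id if gene is not None else None,
                )
            )
    out.sort(key=lambda c: (c.region.chrom, c.region.start, c.region.strand))
    return out


def truncation_counts(cluster: TagCluster, tags: list[ClipTag]):
    """5'-end counts per position of a cluster (positions with k >= 1).

    Counts every tag whose 5' end lies in the cluster region on the same
    chromosome and strand; their sum is the cluster's tag total n.
    """
    r = cluster.region
    if r.width == 0:
        raise ValueError("cluster width 0")
    fives = [
        t.five_prime
        for t in tags
        if t.chrom == r.chrom
        and t.strand == r.strand
        and r.start <= t.five_prime < r.end
    ]
    pos, k = np.unique(np.array(fives, dtype=int), return_counts=True)
    return pos, k, len(fives)


def call_cits(
    clusters: list[TagCluster],
    tags: list[ClipTag],
    fdr: float = 0.001,
) -> list[CitsCall]:
    """Call crosslink-induced truncation sites at BH FDR < ``fdr``.

    Every position of every cluster enters the BH correction; positions
    without any 5' end contribute p = 1.
    """
    entries = []  # (cluster_idx, position, k, n, p)
    n_extra_ones = 0
    for ci, c in enumerate(clusters):
        pos, k, n = truncation_counts(c, tags)
        w = c.region.width
        p0 = 1.0 / w
        if len(pos):
            p = stats.binom.sf(k - 1, n, p0)
            for pp, kk, pv in zip(pos, k, p):
                entries.append((ci, int(pp), int(kk), n, float(pv)))
        n_extra_ones += w - len(pos)
    if not entries:
        return []
    pvals = np.concatenate(
        [np.array([e[4] for e in entries]), np.ones(n_extra_ones)]
    )
    qvals = bh_adjust(pvals)[: len(entries)]
    out = []
    for (ci, position, k, n, p), q in zip(entries, qvals):
        if q < fdr:
            c = clusters[ci]
            out.append(
                CitsCall(
                    c.region.chrom, c.region.strand, position, k, n, p,
                    float(q),
                )
            )
    out.sort(key=lambda x: (x.chrom, x.position, x.strand))
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _count_overlapping(starts_sorted, ends_sorted, start, end) -> int:
    """Number of intervals overlapping [start, end) given separately
    sorted start and end arrays of the same interval set."""
    n = len(starts_sorted)
    n_left = int(np.searchsorted(ends_sorted, start, side="right"))
    n_right = n - int(np.searchsorted(starts_sorted, end, side="left"))
    return n - n_left - n_right


def reproducible_peaks(
    clusters_rep1: list[TagCluster],
    clusters_rep2: list[TagCluster],
    input_tags: list[ClipTag],
    *,
    ip_library_size: int | None = None,
    input_library_size: int | None = None,
    ann: GenomeAnnotation | None = None,
    log2fc_min: float = 2.0,
    repro_min: float = 2.0,
    keep_all: bool = False,
) -> list[HighConfidencePeak]:
    """High-confidence peaks: replicate-overlapping clusters enriched
    over the size-matched input.

    ``log2fc_vs_input`` compares pooled IP tag density with the input
    tag density over the union region (pseudocount 1 tag per region on
    both sides), scaled by the library sizes when given.  The
    reproducibility surrogate is described in the module docstring.
    """
    if input_tags is None or len(input_tags) == 0:
        raise ValueError(
            "a size-matched input tag track is required to call "
            "high-confidence peaks"
        )
    pairs = []  # (union_region, n1, n2, p_bonf1, p_bonf2)
    by_key: dict[tuple[str, str], list[TagCluster]] = {}
    for c in clusters_rep2:
        by_key.setdefault((c.region.chrom, c.region.strand), []).append(c)
    for cs in by_key.values():
        cs.sort(key=lambda c: c.region.start)
    for c1 in clusters_rep1:
        key = (c1.region.chrom, c1.region.strand)
        for c2 in by_key.get(key, []):
            if c2.region.start >= c1.region.end:
                break
            if c1.region.overlaps(c2.region):
                union = Region(
                    c1.region.chrom,
                    min(c1.region.start, c2.region.start),
                    max(c1.region.end, c2.region.end),
                    c1.region.strand,
                )
                pairs.append(
                    (union, c1.n_tags, c2.n_tags, c1.p_bonferroni,
                     c2.p_bonferroni)
                )
    if not pairs:
        return []

    in_by_chrom: dict[str, tuple] = {}
    for t in input_tags:
        in_by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    in_sorted = {
        c: (
            np.sort(np.array([s for s, _ in iv])),
            np.sort(np.array([e for _, e in iv])),
        )
        for c, iv in in_by_chrom.items()
    }
    ip_lib = ip_library_size
    in_lib = input_library_size if input_library_size else len(input_tags)
    scale = (in_lib / ip_lib) if (ip_lib and in_lib) else 1.0

    p1 = np.array([p[3] for p in pairs], dtype=float)
    p2 = np.array([p[4] for p in pairs], dtype=float)
    repro = -np.log10(np.clip(np.maximum(p1, p2), P_FLOOR, 1.0))

    gene_lookup = None
    if ann is not None:
        by_chrom: dict[str, list] = {}
        for g in ann.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.span.start)
        gene_lookup = {
            c: (
                np.array([g.span.start for g in gs]),
                np.array([g.span.end for g in gs]),
                gs,
            )
            for c, gs in by_chrom.items()
        }

    out = []
    for (union, n1, n2, _, _), rep in zip(pairs, repro):
        if union.chrom in in_sorted:
            ss, ee = in_sorted[union.chrom]
            n_in = _count_overlapping(ss, ee, union.start, union.end)
        else:
            n_in = 0
        log2fc = float(np.log2((n1 + n2 + 1) * scale / (n_in + 1)))
        retained = log2fc >= log2fc_min and rep >= repro_min
        if retained or keep_all:
            gene_id = None
            if gene_lookup is not None:
                g = _locate_gene(
                    gene_lookup, union.chrom, union.start, union.strand
                )
                gene_id = g.gene_id if g is not None else None
            out.append(
                HighConfidencePeak(union, log2fc, float(rep), gene_id)
            )
    return out
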