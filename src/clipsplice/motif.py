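"""k-mer and degenerate-motif enrichment around CLIP peaks and CITS.

Foreground sequences are 101-nt windows centered on cluster peak
centers (peak height >= 10); background sequences are the two 100-nt
flanks at (-550,-450) and (450,550) relative to the same centers, taken
on the peak strand.  Enrichment of each k-mer in foreground versus
background uses a binomial upper-tail test plus a normal-approximation
Z score.  Positional enrichment profiles anchor a degenerate motif at
CITS positions (or peak centers) and normalize per-offset motif-start
frequencies by the motif frequency in flanking sequence.

``seeded_pwm`` is a deliberately simplified seeded, crosslink-aware PWM
refinement: for each seed 7-mer it pools all 7-mer instances within
Hamming distance 1 of the seed starting within +/-20 nt of a CITS,
builds a base-frequency matrix from the pooled instances (degenerate
positions emerge from the counts), records where the crosslink falls
inside the motif, and returns the top-scoring seed's model.  The score
— mean per-position information content times the fraction of windows
contributing an instance — is this package's own.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotation import Region
from .io import fetch_rna

log = logging.getLogger(__name__)

RNA_BASES = "ACGU"

# IUPAC degenerate RNA alphabet.  N in a *sequence* never matches.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "U": frozenset("U"),
    "W": frozenset("AU"), "S": frozenset("CG"), "R": frozenset("AG"),
    "Y": frozenset("CU"), "K": frozenset("GU"), "M": frozenset("AC"),
    "B": frozenset("CGU"), "D": frozenset("AGU"), "H": frozenset("ACU"),
    "V": frozenset("ACG"), "N": frozenset("ACGU"),
}


@dataclass(frozen=True)
class DegenerateMotif:
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"unsupported motif letters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.pattern)


@dataclass
class KmerStat:
    kmer: str
    fg_count: int
    fg_total: int
    bg_freq: float
    z: float
    p: float


@dataclass
class PositionalProfile:
    offsets: np.ndarray
    enrichment: np.ndarray
    anchor_freq: np.ndarray
    flank_freq: float


@dataclass
class SeededPwm:
    seed: str
    matrix: np.ndarray            # (L, 4) column-stochastic over ACGU
    crosslink_profile: np.ndarray  # (L,) sums to 1
    score: float
    n_instances: int = 0

    @property
    def consensus(self) -> str:
        """Degenerate consensus: at each position, the IUPAC letter of the
        set of bases with frequency >= 0.3."""
        rev = {v: k for k, v in IUPAC.items()}
        out = []
        for col in self.matrix:
            allowed = frozenset(
                b for b, p in zip(RNA_BASES, col) if p >= 0.3
            ) or frozenset({RNA_BASES[int(np.argmax(col))]})
            out.append(rev[allowed])
        return "".join(out)


@dataclass
class SeqWindow:
    region: Region
    seq: str  # RNA, transcript orientation


def match_degenerate(motif: DegenerateMotif | str, seq: str) -> list[int]:
    """All start offsets where the motif matches (RNA alphabet, N in the
    sequence never matches)."""
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    pat = [IUPAC[c] for c in motif.pattern]
    L = len(pat)
    seq = seq.upper().replace("T", "U")
    return [
        i
        for i in range(len(seq) - L + 1)
        if all(seq[i + j] in pat[j] for j in range(L))
    ]


def matches_degenerate(pattern: str, word: str) -> bool:
    return len(word) == len(pattern) and bool(
        match_degenerate(pattern, word)
    )


def extract_fg_bg(
    clusters,
    genome: dict[str, str],
    *,
    ph_min: int = 10,
    half: int = 50,
    flank: tuple[int, int] = (450, 550),
) -> tuple[list[SeqWindow], list[SeqWindow]]:
    """Foreground/background windows around cluster peak centers.

    Foreground: ``peak_center +/- half`` (2*half+1 nt) for clusters with
    ``peak_height >= ph_min``.  Background: the two ``flank``-defined
    windows on the same strand.  Peaks whose windows run off the
    chromosome are dropped with a warning.
    """
    fg, bg = [], []
    n_dropped = 0
    for c in clusters:
        if c.peak_height < ph_min:
            continue
        chrom, strand = c.region.chrom, c.region.strand
        if chrom not in genome:
            raise KeyError(f"genome is missing chromosome {chrom!r}")
        clen = len(genome[chrom])
        ctr = c.peak_center
        windows = [
            (ctr - half, ctr + half + 1),
            (ctr - flank[1], ctr - flank[0]),
            (ctr + flank[0], ctr + flank[1]),
        ]
        if any(s < 0 or e > clen for s, e in windows):
            n_dropped += 1
            continue
        fg.append(
            SeqWindow(
                Region(chrom, windows[0][0], windows[0][1], strand),
                fetch_rna(genome, chrom, windows[0][0], windows[0][1], strand),
            )
        )
        for s, e in windows[1:]:
            bg.append(
                SeqWindow(
                    Region(chrom, s, e, strand),
                    fetch_rna(genome, chrom, s, e, strand),
                )
            )
    if n_dropped:
        log.warning(
            "dropped %d peaks with windows beyond chromosome ends", n_dropped
        )
    return fg, bg


def repeat_filter(
    windows: list[SeqWindow],
    mask: list[Region] | None,
    max_frac: float = 0.2,
) -> list[SeqWindow]:
    """Keep windows whose repeat-masked fraction is <= ``max_frac``."""
    if not mask:
        log.warning("no repeat mask supplied; keeping all windows")
        return list(windows)
    by_chrom: dict[str, list[Region]] = {}
    for r in mask:
        by_chrom.setdefault(r.chrom, []).append(r)
    out = []
    for w in windows:
        overlap = sum(
            w.region.overlap_nt(r) for r in by_chrom.get(w.region.chrom, [])
        )
        if overlap / w.region.width <= max_frac:
            out.append(w)
    return out


def _seqs(windows) -> list[str]:
    return [w.seq if isinstance(w, SeqWindow) else w for w in windows]


def kmer_enrichment(
    fg_windows, bg_windows, k: int = 7
) -> list[KmerStat]:
    """Binomial enrichment of every foreground k-mer versus background.

    ``fg_total`` counts all k-mer start positions in the foreground;
    background per-position frequency ``bg_freq`` uses a pseudocount of
    1 for k-mers unseen in the background.  Returned sorted by Z
    descending (ties by k-mer).
    """
    fg_seqs, bg_seqs = _seqs(fg_windows), _seqs(bg_windows)
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background must both be non-empty")

    def count(seqs):
        c: Counter = Counter()
        total = 0
        for s in seqs:
            s = s.upper().replace("T", "U")
            total += max(0, len(s) - k + 1)
            for i in range(len(s) - k + 1):
                w = s[i:i + k]
                if "N" not in w:
                    c[w] += 1
        return c, total

    fg_c, fg_total = count(fg_seqs)
    bg_c, bg_total = count(bg_seqs)
    if bg_total <= 0:
        raise ValueError("empty background")
    out = []
    for kmer, n in fg_c.items():
        bg_freq = max(bg_c.get(kmer, 0), 1) / bg_total
        mean = fg_total * bg_freq
        sd = np.sqrt(fg_total * bg_freq * (1 - bg_freq))
        z = (n - mean) / sd if sd > 0 else 0.0
        p = float(stats.binom.sf(n - 1, fg_total, bg_freq))
        out.append(KmerStat(kmer, n, fg_total, bg_freq, float(z), p))
    out.sort(key=lambda s: (-s.z, s.kmer))
    return out


def positional_enrichment(
    motif: DegenerateMotif | str,
    anchors: list[tuple[str, int, str]],
    genome: dict[str, str],
    *,
    half_window: int = 50,
    flank: tuple[int, int] = (450, 550),
) -> PositionalProfile:
    """Motif-start enrichment per offset relative to anchor positions.

    ``anchors`` are (chrom, position, strand) triples (CITS or peak
    centers).  ``enrichment[o]`` is the fraction of anchors with a motif
    start at offset o (transcript orientation, anchor at 0) divided by
    the per-position motif frequency in the flanking windows.
    """
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    if not anchors:
        raise ValueError("need at least one anchor")
    L = motif.length
    offsets = np.arange(-half_window, half_window + 1)
    counts = np.zeros(len(offsets), dtype=float)
    n_used = 0
    flank_hits = 0
    flank_positions = 0
    for chrom, pos, strand in anchors:
        clen = len(genome[chrom])
        # sense offsets o in [-half, half] with the motif spanning
        # [o, o+L); on the minus strand sense-downstream is genomic-left
        if strand == "-":
            lo, hi = pos - half_window - L + 1, pos + half_window + 1
        else:
            lo, hi = pos - half_window, pos + half_window + L
        if lo < 0 or hi > clen:
            continue
        if pos - flank[1] - L < 0 or pos + flank[1] + L > clen:
            continue
        n_used += 1
        seq = fetch_rna(genome, chrom, lo, hi, strand)
        for m in match_degenerate(motif, seq):
            counts[m] += 1  # seq index m corresponds to offset m - half_window
        for a, b in ((pos - flank[1], pos - flank[0]),
                     (pos + flank[0], pos + flank[1])):
            fseq = fetch_rna(genome, chrom, a, b + L, strand)
            flank_hits += len(match_degenerate(motif, fseq))
            flank_positions += b - a
    if n_used == 0:
        raise ValueError("no anchor had room for the flanking windows")
    if flank_hits == 0:
        raise ValueError(
            "motif absent from flanking sequence; use larger flanks"
        )
    anchor_freq = counts / n_used
    flank_freq = flank_hits / flank_positions
    return PositionalProfile(
        offsets, anchor_freq / flank_freq, anchor_freq, flank_freq
    )


def _hamming1_matches(seed: str, seq: str, lo: int, hi: int) -> list[int]:
    """Starts in [lo, hi] where seq matches seed with <= 1 mismatch."""
    L = len(seed)
    out = []
    for i in range(max(0, lo), min(len(seq) - L, hi) + 1):
        w = seq[i:i + L]
        if "N" in w:
            continue
        if sum(a != b for a, b in zip(w, seed)) <= 1:
            out.append(i)
    return out


def seeded_pwm(
    seeds: list[str],
    cits_windows: list[str],
    *,
    center: int | None = None,
    max_offset: int = 20,
) -> SeededPwm:
    """Seeded crosslink-aware PWM refinement (simplified).

    ``cits_windows`` are RNA sequences centered on CITS positions (the
    crosslink sits at index ``center``, default the window midpoint).
    See the module docstring for the procedure and scoring.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    best: SeededPwm | None = None
    n_windows = len(cits_windows)
    for seed in seeds:
        seed = seed.upper().replace("T", "U")
        L = len(seed)
        counts = np.zeros((L, 4))
        xlink = np.zeros(L)
        n_inst = 0
        n_windows_hit = 0
        for w in cits_windows:
            w = w.upper().replace("T", "U")
            ctr = center if center is not None else len(w) // 2
            starts = _hamming1_matches(seed, w, ctr - max_offset,
                                       ctr + max_offset)
            if starts:
                n_windows_hit += 1
            for s in starts:
                inst = w[s:s + L]
                for j, b in enumerate(inst):
                    counts[j, RNA_BASES.index(b)] += 1
                off = ctr - s
                if 0 <= off < L:
                    xlink[off] += 1
                n_inst += 1
        if n_inst == 0:
            continue
        matrix = counts / counts.sum(axis=1, keepdims=True)
        profile = (
            xlink / xlink.sum() if xlink.sum() > 0 else np.full(L, 1.0 / L)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ic = 2.0 + np.nansum(
                np.where(matrix > 0, matrix * np.log2(matrix), 0.0), axis=1
            )
        score = float(ic.mean() * min(1.0, n_windows_hit / max(n_windows, 1)))
        cand = SeededPwm(seed, matrix, profile, score, n_inst)
        if best is None or cand.score > best.score:
            best = cand
    if best is None:
        raise ValueError("no seed matched any CITS window")
    return best


def write_meme(pwm: SeededPwm, path) -> None:
    """Write a PWM in MEME minimal motif format (RNA alphabet)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("strands: +\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n"
        )
        fh.write(f"MOTIF {pwm.consensus} {pwm.seed}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {len(pwm.matrix)} "
            f"nsites= {pwm.n_instances} E= 0\n"
        )
        for row in pwm.matrix:
            fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
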