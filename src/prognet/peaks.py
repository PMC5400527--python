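"""Genomic-interval analytics for transcription-factor co-binding.

All intervals are 0-based half-open. Peak-to-gene assignment uses a
strand-aware promoter window (default -2kb/+2.5kb around the TSS) and a
configurable minimum overlap (default 1 bp). The k-way peak intersection
reports maximal regions covered by at least one peak from *every* input
set; its significance comes from a permutation null that uniformly
repositions peaks within their chromosome, lengths preserved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import GeneModel, GenomicInterval, PeakSet

__all__ = [
    "PromoterWindow",
    "OverlapTestResult",
    "promoter_windows",
    "assign_peaks_to_genes",
    "classify_peaks",
    "multiway_intersection",
    "permutation_overlap_test",
    "tss_coverage_matrix",
    "gene_set_overlaps",
]

CATEGORIES = ("promoter", "exon", "intron", "active_enhancer", "enhancer", "intergenic")


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


def promoter_windows(
    genes: Sequence[GeneModel],
    up: int = 2000,
    down: int = 2500,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[PromoterWindow]:
    """Strand-aware promoter windows: [tss-up, tss+down) on '+',
    [tss-down, tss+up) on '-'; clipped to the chromosome."""
    windows = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - up, g.tss + down
        else:
            start, end = g.tss - down, g.tss + up
        start = max(0, start)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[g.chrom])
        windows.append(PromoterWindow(g.gene_id, g.chrom, start, end, g.strand))
    return windows


# ---------------------------------------------------------------------------
# interval primitives (merged, sorted, per-chromosome (n, 2) arrays)
# ---------------------------------------------------------------------------

def _merge(ivs: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent [start, end) rows (input any order)."""
    if len(ivs) == 0:
        return ivs.reshape(0, 2)
    order = np.argsort(ivs[:, 0], kind="stable")
    s = ivs[order, 0]
    e = np.maximum.accumulate(ivs[order, 1])
    new = np.concatenate([[True], s[1:] > e[:-1]])
    group_start = s[new]
    idx = np.flatnonzero(new)
    group_end = e[np.concatenate([idx[1:] - 1, [len(s) - 1]])]
    return np.column_stack([group_start, group_end]).astype(np.int64)


def _kway_regions(merged_per_set: Sequence[np.ndarray]) -> np.ndarray:
    """Regions covered by every one of k merged interval arrays (sweep line).

    Each input array must be merged (self-overlap-free), so the summed
    coverage depth at any base equals the number of covering sets.
    """
    k = len(merged_per_set)
    sizes = [len(a) for a in merged_per_set]
    if min(sizes) == 0:
        return np.empty((0, 2), dtype=np.int64)
    starts = np.concatenate([a[:, 0] for a in merged_per_set])
    ends = np.concatenate([a[:, 1] for a in merged_per_set])
    pos = np.concatenate([starts, ends])
    delta = np.concatenate([np.ones(len(starts), np.int64),
                            -np.ones(len(ends), np.int64)])
    upos, inv = np.unique(pos, return_inverse=True)
    agg = np.zeros(len(upos), dtype=np.int64)
    np.add.at(agg, inv, delta)
    keep = agg != 0
    upos, agg = upos[keep], agg[keep]
    depth = np.cumsum(agg)
    active = depth == k  # depth holds on [upos[i], upos[i+1])
    idx = np.flatnonzero(active)
    if len(idx) == 0:
        return np.empty((0, 2), dtype=np.int64)
    # zero-net boundaries were dropped, so active segments are maximal
    return np.column_stack([upos[idx], upos[idx + 1]])


def _chrom_arrays(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.array(v, dtype=np.int64) for c, v in by.items()}


def _any_overlap(
    merged: Mapping[str, np.ndarray], chrom: str, start: int, end: int, min_overlap: int = 1
) -> bool:
    arr = merged.get(chrom)
    if arr is None or len(arr) == 0:
        return False
    # merged+sorted: starts and ends are both strictly increasing, so scan
    # backwards from the last interval starting before the query end and
    # stop once ends fall too low to reach min_overlap
    i = int(np.searchsorted(arr[:, 0], end))
    for s, e in arr[:i][::-1]:
        if e - start < min_overlap:
            break
        if min(e, end) - max(s, start) >= min_overlap:
            return True
    return False


def multiway_intersection(peaksets: Sequence[PeakSet]) -> list[GenomicInterval]:
    """Maximal regions covered by >= 1 peak from every input set."""
    if len(peaksets) == 0:
        raise ValueError("need at least one peak set")
    per_set = []
    for ps in peaksets:
        per_set.append({c: _merge(a) for c, a in _chrom_arrays(ps.intervals).items()})
    chroms = set(per_set[0])
    for d in per_set[1:]:
        chroms &= set(d)
    out: list[GenomicInterval] = []
    for chrom in sorted(chroms):
        for s, e in _kway_regions([d[chrom] for d in per_set]):
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def assign_peaks_to_genes(
    peaks: PeakSet,
    windows: Sequence[PromoterWindow],
    min_overlap: int = 1,
) -> tuple[set[str], dict[str, list[GenomicInterval]]]:
    """Genes whose promoter window overlaps >= 1 peak by >= min_overlap bp."""
    by_chrom = _chrom_arrays(peaks.intervals)
    ivs_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in peaks.intervals:
        ivs_by_chrom.setdefault(iv.chrom, []).append(iv)
    positive: set[str] = set()
    assignments: dict[str, list[GenomicInterval]] = {}
    for w in windows:
        hits = [
            iv
            for iv in ivs_by_chrom.get(w.chrom, [])
            if min(iv.end, w.end) - max(iv.start, w.start) >= min_overlap
        ]
        if hits:
            positive.add(w.gene_id)
            assignments[w.gene_id] = hits
    return positive, assignments


def classify_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    mark1: PeakSet,
    mark2: PeakSet,
    up: int = 2000,
    down: int = 2500,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    min_overlap: int = 1,
    active_enhancer_rule: str = "both",
) -> tuple[list[str], Counter]:
    """Assign each peak exactly one category by priority:
    promoter > exon > intron > active_enhancer > enhancer > intergenic.

    Enhancer = overlaps mark1 (H3K4me1-like) outside promoters/gene
    bodies; active enhancer additionally overlaps mark2 (H3K27ac-like)
    when ``active_enhancer_rule='both'``, or is defined by mark2 alone
    with ``'mark2'``.
    """
    if active_enhancer_rule not in ("both", "mark2"):
        raise ValueError("active_enhancer_rule must be 'both' or 'mark2'")
    windows = promoter_windows(genes, up, down, chrom_sizes)
    prom = {
        c: _merge(a)
        for c, a in _chrom_arrays(
            [GenomicInterval(w.chrom, w.start, w.end) for w in windows]
        ).items()
    }
    exon_ivs = [e for g in genes for e in g.exons]
    exons = {c: _merge(a) for c, a in _chrom_arrays(exon_ivs).items()}
    intron_ivs = []
    for g in genes:
        span_s, span_e = g.span
        cursor = span_s
        for e in g.exons:
            if e.start > cursor:
                intron_ivs.append(GenomicInterval(g.chrom, cursor, e.start))
            cursor = max(cursor, e.end)
        if span_e > cursor:
            intron_ivs.append(GenomicInterval(g.chrom, cursor, span_e))
    introns = {c: _merge(a) for c, a in _chrom_arrays(intron_ivs).items()}
    m1 = {c: _merge(a) for c, a in _chrom_arrays(mark1.intervals).items()}
    m2 = {c: _merge(a) for c, a in _chrom_arrays(mark2.intervals).items()}

    cats: list[str] = []
    for iv in peaks.intervals:
        args = (iv.chrom, iv.start, iv.end, min_overlap)
        if _any_overlap(prom, *args):
            cat = "promoter"
        elif _any_overlap(exons, *args):
            cat = "exon"
        elif _any_overlap(introns, *args):
            cat = "intron"
        else:
            in1 = _any_overlap(m1, *args)
            in2 = _any_overlap(m2, *args)
            if active_enhancer_rule == "both":
                if in1 and in2:
                    cat = "active_enhancer"
                elif in1:
                    cat = "enhancer"
                else:
                    cat = "intergenic"
            else:  # mark2 alone defines activity
                if in2:
                    cat = "active_enhancer"
                elif in1:
                    cat = "enhancer"
                else:
                    cat = "intergenic"
        cats.append(cat)
    return cats, Counter(cats)


@dataclass
class OverlapTestResult:
    observed: int
    null_counts: np.ndarray
    p_empirical: float
    n_perm: int


def _shuffle_peakset(
    ps: PeakSet,
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
    null: str,
) -> PeakSet:
    if null == "uniform":
        new = []
        for iv in ps.intervals:
            length = iv.end - iv.start
            clen = chrom_sizes[iv.chrom]
            if length > clen:
                raise ValueError(
                    f"peak length {length} exceeds chromosome {iv.chrom} ({clen})"
                )
            start = int(rng.integers(0, clen - length + 1))
            new.append(GenomicInterval(iv.chrom, start, start + length))
        return PeakSet(ps.factor_name, new)
    if null == "circular":
        offsets = {c: int(rng.integers(0, l)) for c, l in chrom_sizes.items()}
        new = []
        for iv in ps.intervals:
            clen = chrom_sizes[iv.chrom]
            s = (iv.start + offsets[iv.chrom]) % clen
            e = s + (iv.end - iv.start)
            if e <= clen:
                new.append(GenomicInterval(iv.chrom, s, e))
            else:  # wrap around: split into two pieces
                new.append(GenomicInterval(iv.chrom, s, clen))
                new.append(GenomicInterval(iv.chrom, 0, e - clen))
        return PeakSet(ps.factor_name, new)
    raise ValueError(f"unknown null model {null!r}")


def permutation_overlap_test(
    peaksets: Sequence[PeakSet],
    chrom_sizes: Mapping[str, int],
    n_perm: int = 999,
    seed: int = 0,
    null: str = "uniform",
) -> OverlapTestResult:
    """Permutation test of the k-way intersection count.

    Set 1 is held fixed; each permutation independently repositions every
    peak of sets 2..k uniformly within its chromosome (length preserved;
    ``null='circular'`` rotates each set instead). The add-one empirical
    p-value is (1 + #{null >= observed}) / (1 + n_perm), never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for ps in peaksets:
        for iv in ps.intervals:
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"peak on unknown chromosome {iv.chrom!r}")
            if iv.end - iv.start > chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"peak length {iv.end - iv.start} exceeds chromosome "
                    f"{iv.chrom} length {chrom_sizes[iv.chrom]}"
                )
    observed = len(multiway_intersection(peaksets))
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    if null == "uniform":
        # array fast path: reposition lengths per chromosome, sweep-count
        fixed = {c: _merge(a) for c, a in _chrom_arrays(peaksets[0].intervals).items()}
        lens_per_set = [
            {c: (a[:, 1] - a[:, 0]) for c, a in _chrom_arrays(ps.intervals).items()}
            for ps in peaksets[1:]
        ]
        chroms = set(fixed)
        for d in lens_per_set:
            chroms &= set(d)
        chroms = sorted(chroms)
        for b in range(n_perm):
            count = 0
            for chrom in chroms:
                clen = chrom_sizes[chrom]
                merged = [fixed[chrom]]
                for d in lens_per_set:
                    lens = d[chrom]
                    starts = rng.integers(0, clen - lens + 1)
                    merged.append(_merge(np.column_stack([starts, starts + lens])))
                count += len(_kway_regions(merged))
            null_counts[b] = count
    else:
        for b in range(n_perm):
            shuffled = [peaksets[0]] + [
                _shuffle_peakset(ps, chrom_sizes, rng, null) for ps in peaksets[1:]
            ]
            null_counts[b] = len(multiway_intersection(shuffled))
    p = (1.0 + int(np.sum(null_counts >= observed))) / (1.0 + n_perm)
    return OverlapTestResult(observed, null_counts, float(p), n_perm)


def tss_coverage_matrix(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    rank_peaks: Optional[PeakSet] = None,
    window: int = 10_000,
    bin_size: int = 100,
    use_score: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Per-gene binned peak coverage in a +/-window around the TSS.

    Cell (g, b) is the number of base pairs of bin b covered by peaks
    (optionally weighted by peak score). Minus-strand rows are reversed
    so bins always run 5' to 3'. Rows are ordered by descending maximum
    ``rank_peaks`` score within each gene's window (default: the coverage
    peaks themselves). Returns (ordered gene ids, matrix).
    """
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    n_bins = 2 * window // bin_size
    if rank_peaks is None:
        rank_peaks = peaks
    ivs_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in peaks.intervals:
        ivs_by_chrom.setdefault(iv.chrom, []).append(iv)
    rank_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in rank_peaks.intervals:
        rank_by_chrom.setdefault(iv.chrom, []).append(iv)

    mat = np.zeros((len(genes), n_bins))
    rank_score = np.zeros(len(genes))
    for gi, g in enumerate(genes):
        w_start, w_end = g.tss - window, g.tss + window
        edges = w_start + bin_size * np.arange(n_bins + 1)
        for iv in ivs_by_chrom.get(g.chrom, []):
            s, e = max(iv.start, w_start), min(iv.end, w_end)
            if s >= e:
                continue
            weight = iv.score if (use_score and iv.score is not None) else 1.0
            b0 = (s - w_start) // bin_size
            b1 = (e - 1 - w_start) // bin_size
            for b in range(b0, b1 + 1):
                ov = min(e, edges[b + 1]) - max(s, edges[b])
                mat[gi, b] += weight * ov
        for iv in rank_by_chrom.get(g.chrom, []):
            if min(iv.end, w_end) > max(iv.start, w_start):
                rank_score[gi] = max(rank_score[gi], iv.score or 0.0)
        if g.strand == "-":
            mat[gi] = mat[gi][::-1]

    order = np.argsort(-rank_score, kind="stable")
    return [genes[i].gene_id for i in order], mat[order]


def gene_set_overlaps(sets: Mapping[str, set[str]]) -> dict[frozenset, int]:
    """Exclusive Venn-region counts over k named gene sets.

    Keys are frozensets of set names; value = number of genes belonging
    to exactly those sets. Counts sum to the size of the union.
    """
    if not sets:
        raise ValueError("need at least one gene set")
    universe = set().union(*sets.values())
    counts: Counter = Counter()
    for gene in universe:
        member = frozenset(name for name, s in sets.items() if gene in s)
        counts[member] += 1
    return dict(counts)
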