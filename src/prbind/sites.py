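"""Geometric and annotation analyses of binding-site sets.

Covers resizing peaks to a fixed width around their summit, strand-aware
nearest-TSS assignment with signed distances (negative = upstream in the
gene's transcription orientation), the six-way distance binning used for
genomic-distribution reports, intron classification, per-chromosome
count/covariate correlation, and two-set interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .formats import GeneRecord, GenomicInterval

__all__ = [
    "AnnotatedSite",
    "OverlapReport",
    "BIN_LABELS",
    "resize_sites",
    "nearest_tss",
    "bin_distances",
    "classify_intronic",
    "chrom_correlation",
    "overlap_sites",
    "annotated_to_frame",
]

# Ordered upstream-to-downstream; "up" = upstream of the TSS in the gene's
# transcription orientation.
BIN_LABELS = (
    "up >50kb",
    "up 5-50kb",
    "up <=5kb",
    "down <=5kb",
    "down 5-50kb",
    "down >50kb",
)


@dataclass
class AnnotatedSite:
    site: GenomicInterval
    nearest_gene: str | None
    signed_distance: int | None
    bin: str | None
    intronic: bool = False

    @property
    def annotated(self) -> bool:
        return self.nearest_gene is not None


@dataclass
class OverlapReport:
    n_common: int
    common_regions: list[GenomicInterval]
    mean_overlap_len: float


def resize_sites(
    sites: Sequence[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    target_length: int = 1000,
) -> list[GenomicInterval]:
    """Resize each site to ``target_length`` centered on its summit (or
    midpoint when no summit is recorded).

    Windows that would run off a chromosome end are shifted inward so the
    output length is always exactly ``target_length``; a chromosome shorter
    than the target is an error for its sites.
    """
    if target_length <= 0 or target_length % 2:
        raise ValueError("target_length must be positive and even")
    half = target_length // 2
    out = []
    for s in sites:
        clen = chrom_lengths[s.chrom]
        if clen < target_length:
            raise ValueError(
                f"{s.id}: chromosome {s.chrom} ({clen} bp) shorter than "
                f"target length {target_length}"
            )
        start = s.refpoint - half
        start = min(max(start, 0), clen - target_length)
        summit = s.refpoint - start
        # keep the summit inside the shifted window
        summit = min(max(summit, 0), target_length - 1)
        out.append(
            GenomicInterval(s.chrom, start, start + target_length,
                            id=s.id, score=s.score, strand=s.strand,
                            summit=summit)
        )
    return out


def signed_distance(refpoint: int, tss: int, strand: str) -> int:
    """Distance of ``refpoint`` from the TSS in transcription orientation:
    negative upstream, positive downstream."""
    return refpoint - tss if strand == "+" else tss - refpoint


def nearest_tss(
    sites: Sequence[GenomicInterval], genes: Sequence[GeneRecord]
) -> list[AnnotatedSite]:
    """Assign each site the gene whose TSS minimizes the absolute distance
    to the site's reference point (summit, else midpoint).

    Equidistant TSSs tie-break on lexicographic gene id. Sites on
    chromosomes without genes are returned unannotated (flagged by
    ``annotated == False``).
    """
    if not genes:
        raise ValueError("gene annotation is empty")
    # per-chromosome TSS arrays sorted by (tss, gene_id) so searchsorted
    # neighbours + lexicographic tie-break are both O(log n)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.tss, g.gene_id))
        arrays[chrom] = (np.array([g.tss for g in gs]), gs)

    out = []
    for s in sites:
        if s.chrom not in arrays:
            out.append(AnnotatedSite(s, None, None, None))
            continue
        tss_arr, gs = arrays[s.chrom]
        ref = s.refpoint
        j = int(np.searchsorted(tss_arr, ref))
        # candidates straddling the insertion point
        lo, hi = max(0, j - 1), min(len(gs), j + 1)
        best_d = min(abs(ref - gs[k].tss) for k in range(lo, hi))
        # equidistant genes sit at exactly ref +/- best_d
        ties = []
        for target in {ref - best_d, ref + best_d}:
            k = int(np.searchsorted(tss_arr, target, side="left"))
            while k < len(gs) and gs[k].tss == target:
                ties.append(gs[k])
                k += 1
        g = min(ties, key=lambda g: g.gene_id)
        d = signed_distance(ref, g.tss, g.strand)
        out.append(AnnotatedSite(s, g.gene_id, d, assign_bin(d)))
    return out


def assign_bin(d: int, edges: tuple[int, int] = (5_000, 50_000)) -> str:
    """Six-way distance bin; d = 0 and exact edge ties go to the
    downstream / nearer-TSS bin (<= edge counts as proximal)."""
    proximal, distal = edges
    if d < 0:
        a = -d
        if a <= proximal:
            return BIN_LABELS[2]
        if a <= distal:
            return BIN_LABELS[1]
        return BIN_LABELS[0]
    if d <= proximal:
        return BIN_LABELS[3]
    if d <= distal:
        return BIN_LABELS[4]
    return BIN_LABELS[5]


def bin_distances(
    annotated: Iterable[AnnotatedSite],
    edges: tuple[int, int] = (5_000, 50_000),
) -> pd.DataFrame:
    """Per-bin counts and percentages over all annotated sites.

    Percentages are 100 x count / total, rounded to two decimals; the six
    bins partition the annotated sites so counts sum to the total.
    """
    if edges[0] >= edges[1]:
        raise ValueError("bin edges must be strictly increasing")
    counts = {label: 0 for label in BIN_LABELS}
    for a in annotated:
        if a.signed_distance is None:
            continue
        counts[assign_bin(a.signed_distance, edges)] += 1
    total = sum(counts.values())
    rows = [
        {
            "bin": label,
            "count": counts[label],
            "percent": round(100.0 * counts[label] / total, 2) if total else 0.0,
        }
        for label in BIN_LABELS
    ]
    return pd.DataFrame(rows)


def classify_intronic(
    annotated: Sequence[AnnotatedSite], genes: Sequence[GeneRecord]
) -> float:
    """Flag sites whose reference point lies inside any intron (gap between
    consecutive exons of one gene); returns the intronic fraction.

    Membership is evaluated at the reference point, not by interval overlap.
    Mutates the ``intronic`` field of the inputs in place.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        t = trees.setdefault(g.chrom, IntervalTree())
        for a, b in g.introns():
            t.addi(a, b)
    n = 0
    for a in annotated:
        tree = trees.get(a.site.chrom)
        a.intronic = bool(tree is not None and tree.overlaps_point(a.site.refpoint))
        n += a.intronic
    return n / len(annotated) if annotated else 0.0


def chrom_correlation(
    sites: Sequence[GenomicInterval], covariate: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson correlation between per-chromosome site counts and a
    per-chromosome covariate (e.g. chromosome length or TSS count).

    p-value from t = r * sqrt((n-2) / (1-r^2)), two-sided. Requires >= 3
    chromosomes; zero variance in either vector is undefined and raises.
    """
    chroms = sorted(covariate)
    if len(chroms) < 3:
        raise ValueError("need >= 3 chromosomes for a correlation")
    counts = pd.Series([s.chrom for s in sites]).value_counts()
    x = np.array([counts.get(c, 0) for c in chroms], dtype=float)
    y = np.array([covariate[c] for c in chroms], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _merge(intervals: list[tuple[str, int, int]]) -> list[GenomicInterval]:
    intervals.sort()
    merged: list[list] = []
    for chrom, a, b in intervals:
        if merged and merged[-1][0] == chrom and a <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], b)
        else:
            merged.append([chrom, a, b])
    return [GenomicInterval(c, a, b, id=f"common{i:05d}")
            for i, (c, a, b) in enumerate(merged)]


def overlap_sites(
    sites_a: Sequence[GenomicInterval], sites_b: Sequence[GenomicInterval]
) -> OverlapReport:
    """Common regions between two site sets.

    A pair overlapping by >= 1 bp contributes its intersection; pairwise
    intersections are merged into distinct common regions. ``n_common`` is
    the number of merged regions and ``mean_overlap_len`` their mean length,
    so the report is symmetric in its arguments.
    """
    trees: dict[str, IntervalTree] = {}
    for s in sites_b:
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end)
    pieces: list[tuple[str, int, int]] = []
    for s in sites_a:
        tree = trees.get(s.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(s.start, s.end):
            pieces.append((s.chrom, max(s.start, hit.begin), min(s.end, hit.end)))
    regions = _merge(pieces)
    mean_len = float(np.mean([r.length for r in regions])) if regions else 0.0
    return OverlapReport(n_common=len(regions), common_regions=regions,
                         mean_overlap_len=mean_len)


def annotated_to_frame(annotated: Sequence[AnnotatedSite]) -> pd.DataFrame:
    """Tabular view of annotated sites for TSV export."""
    return pd.DataFrame(
        [
            {
                "site_id": a.site.id,
                "chrom": a.site.chrom,
                "start": a.site.start,
                "end": a.site.end,
                "nearest_gene": a.nearest_gene if a.annotated else ".",
                "signed_distance": a.signed_distance if a.annotated else ".",
                "bin": a.bin if a.annotated else ".",
                "intronic": a.intronic,
            }
            for a in annotated
        ]
    )
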