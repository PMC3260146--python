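"""Fold-change differential-expression calling and binding-site integration.

Calls are made on the linear-scale ratio of normalized treated over control
mean intensities, reported in the signed-ratio convention (r when r >= 1,
-1/r otherwise) so a threshold reads symmetrically as e.g. +/-1.40.
Integration measures, for every differentially expressed gene, the distance
from its TSS to the nearest binding site and bins it with the same
5 kb / 50 kb edges used for site annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import GeneRecord, GenomicInterval
from .sites import BIN_LABELS, assign_bin, signed_distance

__all__ = [
    "DECall",
    "call_de",
    "intersect_de",
    "integrate_sites",
    "NO_SITE_BIN",
]

NO_SITE_BIN = "no site"


@dataclass
class DECall:
    """One gene's differential-expression call."""

    gene_id: str
    signed_fc: float
    direction: str  # up | down | unchanged
    present: bool
    nearest_site_distance: int | None = None
    bin: str | None = None


def _signed_ratio(r: float) -> float:
    return r if r >= 1.0 else -1.0 / r


def call_de(
    expr: pd.DataFrame, fc_threshold: float
) -> tuple[list[DECall], list[DECall]]:
    """Call up- and down-regulated genes by signed fold change.

    ``expr`` columns: gene_id, mean_control, mean_treated, present.
    Absent-flagged genes are excluded before calling; genes with
    non-positive intensity are excluded with a warning entry. A gene is up
    iff signed_fc >= fc_threshold and down iff signed_fc <= -fc_threshold.
    Returns ``(up, down)``.
    """
    if fc_threshold <= 1.0:
        raise ValueError("fc_threshold must exceed 1")
    up: list[DECall] = []
    down: list[DECall] = []
    kept = expr[expr["present"].astype(bool)]
    bad = kept[(kept["mean_control"] <= 0) | (kept["mean_treated"] <= 0)]
    if len(bad):
        import warnings

        warnings.warn(
            f"{len(bad)} gene(s) with non-positive intensity excluded"
        )
    kept = kept[(kept["mean_control"] > 0) & (kept["mean_treated"] > 0)]
    ratio = kept["mean_treated"].to_numpy() / kept["mean_control"].to_numpy()
    for gene_id, r in zip(kept["gene_id"], ratio):
        fc = _signed_ratio(float(r))
        if fc >= fc_threshold:
            up.append(DECall(gene_id, fc, "up", True))
        elif fc <= -fc_threshold:
            down.append(DECall(gene_id, fc, "down", True))
    return up, down


def intersect_de(
    calls_a: Sequence[DECall], calls_b: Sequence[DECall]
) -> pd.DataFrame:
    """Genes called in both sets, with per-set directions and a concordance
    flag (same direction in both)."""
    a = {c.gene_id: c for c in calls_a}
    b = {c.gene_id: c for c in calls_b}
    rows = []
    for gid in sorted(set(a) & set(b)):
        rows.append(
            {
                "gene_id": gid,
                "direction_a": a[gid].direction,
                "direction_b": b[gid].direction,
                "signed_fc_a": a[gid].signed_fc,
                "signed_fc_b": b[gid].signed_fc,
                "concordant": a[gid].direction == b[gid].direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "direction_a", "direction_b",
                 "signed_fc_a", "signed_fc_b", "concordant"],
    )


def _nearest_site_distance(
    gene: GeneRecord, site_refpoints: Mapping[str, np.ndarray]
) -> int | None:
    pts = site_refpoints.get(gene.chrom)
    if pts is None or pts.size == 0:
        return None
    j = int(np.searchsorted(pts, gene.tss))
    best = None
    for k in (j - 1, j):
        if 0 <= k < pts.size:
            d = abs(int(pts[k]) - gene.tss)
            if best is None or d < abs(best):
                best = signed_distance(int(pts[k]), gene.tss, gene.strand)
    return best


def integrate_sites(
    de_calls: Sequence[DECall],
    genes: Sequence[GeneRecord],
    sites: Sequence[GenomicInterval],
    edges: tuple[int, int] = (5_000, 50_000),
) -> tuple[pd.DataFrame, set[str], set[str]]:
    """Attach nearest-site distances to DE genes and bin them.

    For each DE gene the signed distance (in transcription orientation)
    from its TSS to the nearest site reference point is computed and binned
    with the annotation edges; genes with no site on their chromosome fall
    in a separate "no site" category. Mutates the calls in place.

    Returns ``(report, proximal_genes, associated_genes)`` where the report
    carries per-bin percentages over all DE genes (with separate up / down
    breakdowns), ``proximal_genes`` is the set with a site within the
    proximal edge (default 5 kb) of the TSS, and ``associated_genes`` the
    set with a site within the association window (default 50 kb) — the
    input to pathway analysis.
    """
    gene_map = {g.gene_id: g for g in genes}
    refpoints: dict[str, np.ndarray] = {}
    for s in sites:
        refpoints.setdefault(s.chrom, []).append(s.refpoint)  # type: ignore[arg-type]
    refpoints = {c: np.array(sorted(v)) for c, v in refpoints.items()}

    proximal: set[str] = set()
    associated: set[str] = set()
    for call in de_calls:
        gene = gene_map.get(call.gene_id)
        d = _nearest_site_distance(gene, refpoints) if gene else None
        call.nearest_site_distance = d
        call.bin = NO_SITE_BIN if d is None else assign_bin(d, edges)
        if d is not None and abs(d) <= edges[0]:
            proximal.add(call.gene_id)
        if d is not None and abs(d) <= edges[1]:
            associated.add(call.gene_id)

    labels = list(BIN_LABELS) + [NO_SITE_BIN]
    rows = []
    for label in labels:
        row = {"bin": label}
        for name, subset in (
            ("all", de_calls),
            ("up", [c for c in de_calls if c.direction == "up"]),
            ("down", [c for c in de_calls if c.direction == "down"]),
        ):
            k = sum(1 for c in subset if c.bin == label)
            row[f"count_{name}"] = k
            row[f"percent_{name}"] = (
                round(100.0 * k / len(subset), 2) if subset else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows), proximal, associated
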