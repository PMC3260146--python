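"""Hypergeometric pathway over-representation with BH FDR.

The universe is the set of genes carrying at least one catalog pathway;
for each pathway with at least one selected gene the upper-tail probability
P(X >= k) of drawing k pathway members among n selected genes from a
universe of N containing K members is computed, and adjusted across
pathways by Benjamini-Hochberg. Pathways significant in two analyses are
combined conservatively by reporting the larger p and FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayResult",
    "read_catalog",
    "hypergeom_enrich",
    "bh_fdr",
    "combine_shared",
    "results_to_frame",
]


@dataclass
class PathwayResult:
    pathway_id: str
    name: str
    k: int  # selected genes in pathway
    K: int  # universe genes in pathway
    n: int  # selected genes total
    N: int  # universe size
    p: float
    fdr: float = float("nan")


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a pathway catalog TSV with columns pathway_id, name, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pathway_id", "name", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    selected_genes: Iterable[str],
    catalog: pd.DataFrame,
    universe: Iterable[str] | None = None,
) -> list[PathwayResult]:
    """Upper-tail hypergeometric enrichment of each catalog pathway.

    ``universe`` defaults to all genes with >= 1 catalog pathway; the
    selection is intersected with the universe. Only pathways with >= 1
    selected gene are reported; FDR is BH across those rows. Results are
    sorted ascending by p.
    """
    catalog_genes = catalog.groupby("pathway_id")["gene_id"].agg(set)
    names = catalog.groupby("pathway_id")["name"].first()
    if universe is None:
        universe_set = set(catalog["gene_id"])
    else:
        universe_set = set(universe)
        orphans = universe_set - set(catalog["gene_id"])
        if orphans:
            raise ValueError(
                f"{len(orphans)} universe gene(s) have no catalog pathway"
            )
    selected = set(selected_genes) & universe_set
    if not selected:
        return []
    N, n = len(universe_set), len(selected)
    results = []
    for pid, members in catalog_genes.items():
        members = members & universe_set
        k = len(members & selected)
        if k == 0:
            continue
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(PathwayResult(pid, names[pid], k, K, n, N, min(p, 1.0)))
    if results:
        fdrs = bh_fdr([r.p for r in results])
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    results.sort(key=lambda r: r.p)
    return results


def combine_shared(
    results_a: Sequence[PathwayResult],
    results_b: Sequence[PathwayResult],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Pathways significant (FDR < cutoff) in BOTH analyses, reported with
    the larger of the two p-values and FDRs."""
    a = {r.pathway_id: r for r in results_a if r.fdr < fdr_cutoff}
    b = {r.pathway_id: r for r in results_b if r.fdr < fdr_cutoff}
    rows = []
    for pid in sorted(set(a) & set(b)):
        rows.append(
            {
                "pathway_id": pid,
                "name": a[pid].name,
                "p": max(a[pid].p, b[pid].p),
                "fdr": max(a[pid].fdr, b[pid].fdr),
            }
        )
    df = pd.DataFrame(rows, columns=["pathway_id", "name", "p", "fdr"])
    return df.sort_values("p", ignore_index=True) if len(df) else df


def results_to_frame(results: Sequence[PathwayResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "name": r.name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "fdr": r.fdr,
            }
            for r in results
        ]
    )
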