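"""End-to-end orchestration of the binding-site analysis stages.

``run_all`` chains: site resizing, strand-aware TSS annotation with
distance binning and intron classification, per-chromosome correlation,
background construction and motif enrichment, the PR-triad motif rule and
consensus derivation, fold-change DE calling, binding-expression
integration, and pathway enrichment. Every stage writes its table into the
output directory and the run ends with a manifest recording the seed and
every resolved threshold, so a rerun under the same seed and config is
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from importlib.resources import files as resource_files
from pathlib import Path

import numpy as np
import yaml

from . import __version__, formats
from .expression import call_de, integrate_sites
from .formats import read_bed, read_expression, read_fasta, read_gene_table, write_tsv
from .motifs import (
    PR_MATRIX_IDS,
    build_consensus,
    enrich_all,
    enrichment_table,
    extract_sequences,
    generate_background,
    pre_hit_rule,
    scan_sites,
)
from .pathways import hypergeom_enrich, read_catalog, results_to_frame
from .sites import (
    annotated_to_frame,
    bin_distances,
    chrom_correlation,
    classify_intronic,
    nearest_tss,
    resize_sites,
)

__all__ = ["RunConfig", "run_all", "PipelineError", "default_matrix_path"]

log = logging.getLogger("prbind")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_matrix_path() -> Path:
    """The synthetic PRE matrix library bundled with the package."""
    return Path(str(resource_files("prbind").joinpath("data/synthetic_pre_matrices.dat")))


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run."""

    genome: str
    sites: str
    genes: str
    matrices: str
    expr: str | None = None
    catalog: str | None = None
    thresholds_sidecar: str | None = None
    out_dir: str = "prbind_out"
    site_length: int = 1000
    fc_threshold: float = 1.30
    dominance_threshold: float = 0.5
    consensus_matrix_id: str = "V$PR_01"
    bin_edges: tuple[int, int] = (5_000, 50_000)
    fdr_cutoff: float = 0.05
    min_shift: int = 1000
    max_shift: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "bin_edges" in data:
            data["bin_edges"] = tuple(data["bin_edges"])
        return cls(**data)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
        return result

    return wrap


def run_all(config: RunConfig) -> Path:
    """Run every stage and return the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }

    # ---- load inputs
    load = _stage("load")

    def _load():
        genome = read_fasta(config.genome)
        raw_sites = read_bed(config.sites)
        genes = read_gene_table(config.genes)
        return genome, raw_sites, genes

    genome, raw_sites, genes = load(_load)
    chrom_sizes = {c: len(s) for c, s in genome.items()}

    # ---- resize + annotate
    resized = _stage("resize")(resize_sites, raw_sites, chrom_sizes, config.site_length)
    annotated = _stage("annotate")(nearest_tss, resized, genes)
    bin_report = bin_distances(annotated, config.bin_edges)
    intronic_fraction = classify_intronic(annotated, genes)
    write_tsv(annotated_to_frame(annotated), out / "annotated_sites.tsv")
    write_tsv(bin_report, out / "distance_bins.tsv")
    manifest["stages"]["annotate"] = {
        "n_sites": len(resized),
        "intronic_fraction": intronic_fraction,
    }
    if len(chrom_sizes) >= 3:
        r, p = chrom_correlation(resized, chrom_sizes)
        manifest["stages"]["annotate"]["chrom_length_correlation_r"] = r
        manifest["stages"]["annotate"]["chrom_length_correlation_p"] = p

    # ---- enrichment (matrix library is loaded here so a bad library file
    # aborts naming this stage)
    def _enrich():
        pwms = formats.parse_transfac(config.matrices)
        if config.thresholds_sidecar:
            formats.read_thresholds(pwms, config.thresholds_sidecar)
        rng = np.random.default_rng([config.seed, 17])
        kept, background = generate_background(
            resized, chrom_sizes, config.min_shift, config.max_shift, seed=rng
        )
        results = enrich_all(pwms, kept, background, genome)
        return pwms, kept, background, results

    pwms, kept, background, results = _stage("enrich")(_enrich)
    write_tsv(enrichment_table(results), out / "enrichment.tsv")
    manifest["stages"]["enrich"] = {
        "n_pwms": len(pwms),
        "n_sites_used": len(kept),
        "top_matrix": results[0].matrix_id if results else None,
    }

    # ---- PR triad + consensus
    def _pre():
        seqs = extract_sequences(kept, genome)
        ids = [s.id for s in kept]
        by_matrix = {}
        for pwm in pwms:
            if pwm.matrix_id in PR_MATRIX_IDS:
                by_matrix[pwm.matrix_id] = scan_sites(seqs, pwm, ids)
        flags, table = pre_hit_rule(by_matrix, ids)
        consensus = None
        cons_hits = by_matrix.get(config.consensus_matrix_id, [])
        if len(cons_hits) >= 2:
            consensus = build_consensus(cons_hits, config.dominance_threshold)
        return flags, table, consensus

    flags, pre_table, consensus = _stage("pre_rule")(_pre)
    write_tsv(pre_table, out / "pre_motif_table.tsv")
    if consensus is not None:
        (out / "consensus.txt").write_text(consensus.consensus + "\n", encoding="utf-8")
    manifest["stages"]["pre_rule"] = {
        "n_pr_positive": int(sum(flags.values())),
        "consensus": consensus.consensus if consensus else None,
    }

    # ---- expression + integration
    if config.expr:
        def _de():
            expr = read_expression(config.expr)
            up, down = call_de(expr, config.fc_threshold)
            report, proximal, associated = integrate_sites(
                up + down, genes, resized, config.bin_edges
            )
            return up, down, report, proximal, associated

        up, down, report, proximal, associated = _stage("expression")(_de)
        write_tsv(
            _de_frame(up + down), out / "de_genes.tsv"
        )
        write_tsv(report, out / "integration_bins.tsv")
        (out / "associated_genes.txt").write_text(
            "\n".join(sorted(associated)) + "\n"
        )
        manifest["stages"]["expression"] = {
            "n_up": len(up),
            "n_down": len(down),
            "n_proximal": len(proximal),
            "n_associated": len(associated),
        }

        # ---- pathways
        if config.catalog:
            def _pathways():
                catalog = read_catalog(config.catalog)
                return hypergeom_enrich(associated, catalog)

            res = _stage("pathways")(_pathways)
            write_tsv(results_to_frame(res), out / "pathway_enrichment.tsv")
            manifest["stages"]["pathways"] = {
                "n_tested": len(res),
                "n_significant": sum(1 for r in res if r.fdr < config.fdr_cutoff),
            }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _de_frame(calls):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "signed_fc": c.signed_fc,
                "direction": c.direction,
                "nearest_site_distance": c.nearest_site_distance,
                "bin": c.bin,
            }
            for c in calls
        ]
    )
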