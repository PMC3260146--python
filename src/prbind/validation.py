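"""Planted-truth validation experiments.

These routines run the pipeline's statistical machinery against synthetic
data with known ground truth: type-I-error calibration of the enrichment
z test under its own sampling model, recovery of a planted motif against
decoy matrices, and recovery of planted fold changes by threshold DE
calling. They are what the test suite and the reproduction script execute.
"""

from __future__ import annotations

import numpy as np

from . import simdata
from .expression import call_de
from .formats import PWM, parse_transfac
from .motifs import enrich_all, enrichment_z, generate_background
from .pipeline import default_matrix_path
from .simdata import SimConfig, make_decoy_pwms

__all__ = [
    "load_planted_pwm",
    "null_calibration",
    "planted_recovery_run",
    "recovery_rate",
    "de_recovery",
]


def load_planted_pwm(matrix_id: str = "V$PR_01") -> PWM:
    return next(
        p for p in parse_transfac(default_matrix_path()) if p.matrix_id == matrix_id
    )


def null_calibration(
    n_libraries: int = 1000,
    pwms_per_library: int = 10,
    n: int = 100_000,
    rate: float = 0.02,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the enrichment z test under its null.

    The statistic models each nucleotide as an independent Bernoulli trial;
    here both groups draw their covered-nucleotide counts from
    Binomial(n, rate) — the null with equal rates, sampled exactly as the
    statistic assumes — and the fraction of PWM tests with p_raw < alpha
    across the replicate libraries is returned. (Real hit footprints cover
    consecutive nucleotides and violate this independence; see the methods
    note for why the full test is anti-conservative on real scans.)
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    total = n_libraries * pwms_per_library
    counts_t = rng.binomial(n, rate, size=total)
    counts_b = rng.binomial(n, rate, size=total)
    for xt, xb in zip(counts_t, counts_b):
        _, p = enrichment_z(xt / n, xb / n, n)
        rejections += p < alpha
    return rejections / total


def planted_recovery_run(
    seed: int,
    n_sites: int = 500,
    plant_rate: float = 0.3,
    n_decoys: int = 10,
    decoys: list[PWM] | None = None,
    planted: PWM | None = None,
) -> tuple[bool, float]:
    """One planted-motif experiment: does the planted matrix rank first?

    Simulates a genome with ``n_sites`` kilobase sites, plants the PRE
    matrix into a ``plant_rate`` fraction (clean background), draws the
    vicinity-matched background and runs the full enrichment over the
    planted matrix plus decoys. Returns ``(ranked_first, planted_z)``.
    """
    planted = planted or load_planted_pwm()
    if decoys is None:
        decoys = make_decoy_pwms(n_decoys, seed=seed)
    cfg = SimConfig(
        chrom_lengths={"chr1": 30 * n_sites * 1000},
        n_genes=50,
        n_sites=n_sites,
        plant_rate_true=plant_rate,
        linked_fraction=0.0,
        seed=seed,
    )
    genome = simdata.simulate_genome(cfg)
    genes = simdata.simulate_annotation(cfg, genome)
    genome, sites, _ = simdata.plant_sites(cfg, genome, genes, planted)
    kept, background = generate_background(
        sites,
        {c: len(s) for c, s in genome.items()},
        seed=np.random.default_rng([seed, 99]),
    )
    results = enrich_all([planted] + decoys, kept, background, genome)
    planted_res = next(r for r in results if r.matrix_id == planted.matrix_id)
    return results[0].matrix_id == planted.matrix_id, planted_res.z


def recovery_rate(
    n_runs: int = 100, base_seed: int = 0, n_sites: int = 500, n_decoys: int = 10
) -> float:
    """Fraction of seeded runs in which the planted matrix ranks first."""
    planted = load_planted_pwm()
    decoys = make_decoy_pwms(n_decoys, seed=base_seed)
    wins = 0
    for i in range(n_runs):
        first, _ = planted_recovery_run(
            seed=base_seed * n_runs + i + 1,
            n_sites=n_sites,
            decoys=decoys,
            planted=planted,
        )
        wins += first
    return wins / n_runs


def de_recovery(
    seed: int = 0,
    n_genes: int = 1000,
    noise_sd: float = 0.05,
    fc_threshold: float = 1.30,
) -> tuple[float, float]:
    """Sensitivity and false-call rate of threshold DE calling on planted
    fold changes.

    Returns ``(sensitivity, false_call_rate)`` where sensitivity counts
    direction-correct recovery of truth genes and the false-call rate is
    the fraction of calls not in the truth set.
    """
    cfg = SimConfig(
        chrom_lengths={"chr1": 10_000_000},
        n_genes=n_genes,
        n_sites=0,
        de_fraction=0.1,
        noise_sd=noise_sd,
        seed=seed,
    )
    genome = {"chr1": ""}
    genes = simdata.simulate_annotation(cfg, {"chr1": "A" * 10_000_000})
    expr, truth = simdata.simulate_expression(cfg, genes)
    up, down = call_de(expr, fc_threshold)
    called = {c.gene_id: c.direction for c in up + down}
    # truth genes flagged absent are not recoverable; judge on testable set
    present = set(expr.loc[expr["present"], "gene_id"])
    testable = {g: fc for g, fc in truth.de_genes.items() if g in present}
    correct = sum(
        1
        for g, fc in testable.items()
        if called.get(g) == ("up" if fc > 0 else "down")
    )
    sensitivity = correct / len(testable) if testable else float("nan")
    false_calls = sum(1 for g in called if g not in truth.de_genes)
    false_rate = false_calls / len(called) if called else 0.0
    return sensitivity, false_rate
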