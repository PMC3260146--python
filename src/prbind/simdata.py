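"""Seeded synthetic genomes, annotations, binding landscapes and expression.

The generators produce the ground-truth-bearing inputs every downstream
stage consumes: an i.i.d. uniform A/C/G/T genome, a gene table with
strand-aware exon structure, a set of non-overlapping "true" binding sites
into which motif instances are planted at a configurable rate, and a
two-condition normalized expression table with planted fold changes.

Each generator draws from its own RNG stream, derived from the master seed
by a fixed offset, so regenerating one output never perturbs another.
Everything is byte-deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .formats import BASES, GeneRecord, GenomicInterval, PWM

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_annotation",
    "plant_sites",
    "simulate_expression",
    "sample_pwm_instance",
    "make_decoy_pwms",
]

# fixed per-generator stream offsets under the master seed
_STREAM_GENOME = 0
_STREAM_ANNOTATION = 1
_STREAM_SITES = 2
_STREAM_EXPRESSION = 3
_STREAM_DECOYS = 4
_STREAM_CATALOG = 5


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale landscape: kilobase binding sites on a
    megabase-scale genome, 30% of true sites carrying a planted motif
    instance against a clean background, and ~10% of genes differentially
    expressed with fold changes of 1.5-3 and 5% multiplicative intensity
    noise — enough signal for every stage to be exercised with known truth.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 2_000_000,
            "chr2": 1_500_000,
            "chr3": 1_000_000,
            "chr4": 500_000,
        }
    )
    n_genes: int = 300
    n_sites: int = 150
    site_length: int = 1000
    planted_pwm_id: str = "V$PR_01"
    plant_rate_true: float = 0.3
    plant_rate_background: float = 0.0  # expected spontaneous instances per kb
    de_fraction: float = 0.1
    fc_range: tuple[float, float] = (1.5, 3.0)
    noise_sd: float = 0.05
    linked_fraction: float = 0.3  # fraction of sites tethered near a TSS
    link_distances: tuple[int, ...] = (2_000, 20_000, 80_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be non-empty")
        if any(L <= 0 for L in self.chrom_lengths.values()):
            raise ValueError("zero-length chromosome")
        if min(self.n_genes, self.n_sites, self.site_length) < 0:
            raise ValueError("counts must be >= 0")
        for name in ("plant_rate_true", "de_fraction", "linked_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.plant_rate_background < 0:
            raise ValueError("plant_rate_background must be >= 0")
        if self.fc_range[0] <= 1.0 or self.fc_range[1] < self.fc_range[0]:
            raise ValueError("fc_range must satisfy 1 < min <= max")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic files."""

    planted_site_ids: set[str] = field(default_factory=set)
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed FC
    site_gene_links: dict[str, tuple[str, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_site_ids": sorted(self.planted_site_ids),
            "de_genes": self.de_genes,
            "site_gene_links": {k: list(v) for k, v in self.site_gene_links.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_site_ids=set(d["planted_site_ids"]),
            de_genes={k: float(v) for k, v in d["de_genes"].items()},
            site_gene_links={k: (v[0], int(v[1])) for k, v in d["site_gene_links"].items()},
        )


def simulate_genome(config: SimConfig) -> dict[str, str]:
    """I.i.d. uniform A/C/G/T sequence per chromosome."""
    rng = config.rng(_STREAM_GENOME)
    base_arr = np.frombuffer("ACGT".encode(), dtype="S1")
    genome = {}
    for chrom, length in config.chrom_lengths.items():
        idx = rng.integers(0, 4, size=length)
        genome[chrom] = base_arr[idx].tobytes().decode()
    return genome


def simulate_annotation(config: SimConfig, genome: Mapping[str, str]) -> list[GeneRecord]:
    """Uniformly placed TSSs, Bernoulli(0.5) strands, 2-5 exons per gene
    laid out downstream of the TSS in transcription orientation."""
    rng = config.rng(_STREAM_ANNOTATION)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms])
    if config.n_genes > lengths.sum():
        raise ValueError("n_genes exceeds placeable positions")
    weights = lengths / lengths.sum()
    genes: list[GeneRecord] = []
    for i in range(config.n_genes):
        c = rng.choice(len(chroms), p=weights)
        chrom, clen = chroms[c], int(lengths[c])
        tss = int(rng.integers(0, clen))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 6))
        exon_lens = rng.integers(100, 500, size=n_exons)
        gap_lens = rng.integers(200, 2000, size=n_exons - 1)
        exons = []
        pos = 0
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(gap_lens[j])
        if strand == "+":
            abs_exons = [(tss + a, tss + b) for a, b in exons]
        else:
            abs_exons = [(tss - b, tss - a) for a, b in exons]
        abs_exons = [(max(0, a), min(clen, b)) for a, b in abs_exons if a < clen and b > 0]
        genes.append(
            GeneRecord(gene_id=f"g{i:05d}", chrom=chrom, strand=strand,
                       tss=tss, exons=abs_exons)
        )
    return genes


def sample_pwm_instance(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw one sequence column-wise from the PWM's base frequencies."""
    freqs = pwm.counts / pwm.counts.sum(axis=1, keepdims=True)
    idx = [rng.choice(4, p=f) for f in freqs]
    return "".join(BASES[i] for i in idx)


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    n: int,
    length: int,
    tether: list[tuple[str, int]] | None = None,
    max_tries: int = 10_000,
) -> list[tuple[str, int]]:
    """Place n intervals of the given length without mutual overlap.

    ``tether`` entries are (chrom, position) targets: those intervals are
    centered on their target rather than placed uniformly.
    """
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[tuple[str, int]] = []
    tether = tether or []

    def overlaps(chrom: str, start: int) -> bool:
        return any(start < e and start + length > s for s, e in placed[chrom])

    for i in range(n):
        ok = False
        for _ in range(max_tries):
            if i < len(tether):
                chrom, center = tether[i]
                start = center - length // 2
                # nudge a tethered site that falls off the chromosome
                start = min(max(start, 0), chrom_lengths[chrom] - length)
            else:
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                if chrom_lengths[chrom] <= length:
                    continue
                start = int(rng.integers(0, chrom_lengths[chrom] - length))
            if not overlaps(chrom, start):
                ok = True
                break
            if i < len(tether):
                # tethered placement is deterministic; jitter instead of loop
                tether[i] = (chrom, center + int(rng.integers(-length, length)))
        if not ok:
            raise ValueError(
                f"could not place {n} non-overlapping sites of length {length}"
            )
        placed[chrom].append((start, start + length))
        out.append((chrom, start))
    return out


def plant_sites(
    config: SimConfig,
    genome: dict[str, str],
    annotation: list[GeneRecord],
    pwm: PWM,
) -> tuple[dict[str, str], list[GenomicInterval], SimTruth]:
    """Create the true binding-site landscape.

    Places ``n_sites`` non-overlapping intervals of ``site_length``; a
    fraction ``linked_fraction`` is tethered near randomly chosen TSSs at
    the configured link distances (giving known distance-bin structure), the
    rest land uniformly. A fraction ``plant_rate_true`` of sites receives a
    sequence sampled column-wise from ``pwm``, written at the site center.
    ``plant_rate_background`` plants spontaneous instances genome-wide at
    the given expected rate per kb.

    Returns the modified genome, the site list (with summit at the planted
    center), and the ground truth.
    """
    if pwm.matrix_id != config.planted_pwm_id:
        raise ValueError(
            f"planted PWM {config.planted_pwm_id!r} not supplied (got {pwm.matrix_id!r})"
        )
    rng = config.rng(_STREAM_SITES)
    truth = SimTruth()

    n_linked = int(round(config.linked_fraction * config.n_sites))
    tether: list[tuple[str, int]] = []
    linked_genes: list[tuple[str, int]] = []
    if n_linked and annotation:
        gene_idx = rng.choice(len(annotation), size=n_linked, replace=False)
        for gi in gene_idx:
            g = annotation[int(gi)]
            d = int(rng.choice(config.link_distances))
            sign = -1 if rng.random() < 0.5 else 1
            # signed offset in transcription orientation
            offset = sign * d if g.strand == "+" else -sign * d
            tether.append((g.chrom, g.tss + offset))
            linked_genes.append((g.gene_id, sign * d))

    positions = _place_nonoverlapping(
        rng, {c: len(s) for c, s in genome.items()},
        config.n_sites, config.site_length, tether=tether,
    )

    seqs = {c: bytearray(s.encode()) for c, s in genome.items()}
    sites: list[GenomicInterval] = []
    motif_len = len(pwm)
    for i, (chrom, start) in enumerate(positions):
        sid = f"site{i:05d}"
        summit = config.site_length // 2
        if rng.random() < config.plant_rate_true:
            inst = sample_pwm_instance(pwm, rng)
            at = start + summit - motif_len // 2
            seqs[chrom][at:at + motif_len] = inst.encode()
            truth.planted_site_ids.add(sid)
        sites.append(
            GenomicInterval(chrom, start, start + config.site_length,
                            id=sid, strand=".", summit=summit)
        )
        if i < len(linked_genes):
            truth.site_gene_links[sid] = linked_genes[i]

    if config.plant_rate_background > 0:
        for chrom, buf in seqs.items():
            lam = config.plant_rate_background * len(buf) / 1000.0
            k = rng.poisson(lam)
            for _ in range(k):
                at = int(rng.integers(0, len(buf) - motif_len))
                buf[at:at + motif_len] = sample_pwm_instance(pwm, rng).encode()

    modified = {c: bytes(b).decode() for c, b in seqs.items()}
    return modified, sites, truth


def simulate_expression(
    config: SimConfig, annotation: list[GeneRecord]
) -> tuple[pd.DataFrame, SimTruth]:
    """Two-condition normalized intensity table with planted fold changes.

    Control means are lognormal. A ``de_fraction`` of genes is differentially
    expressed: treated = control x FC with |FC| drawn uniformly from
    ``fc_range``, half up- and half down-regulated (down uses the reciprocal
    ratio). All genes carry multiplicative lognormal noise of ``noise_sd``
    on the treated/control ratio; ~5% of genes are flagged absent.
    """
    rng = config.rng(_STREAM_EXPRESSION)
    n = len(annotation)
    gene_ids = [g.gene_id for g in annotation]
    control = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n)

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    fc = np.ones(n)
    signed = np.ones(n)
    if n_de:
        mags = rng.uniform(config.fc_range[0], config.fc_range[1], size=n_de)
        up = rng.random(n_de) < 0.5
        fc[de_idx] = np.where(up, mags, 1.0 / mags)
        signed[de_idx] = np.where(up, mags, -mags)

    noise = rng.lognormal(mean=0.0, sigma=config.noise_sd, size=n)
    treated = control * fc * noise
    present = rng.random(n) >= 0.05

    truth = SimTruth(
        de_genes={gene_ids[int(i)]: float(signed[int(i)]) for i in de_idx}
    )
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean_control": control,
            "mean_treated": treated,
            "present": present,
        }
    )
    return df, truth


def simulate_catalog(
    config: SimConfig,
    annotation: list[GeneRecord],
    n_pathways: int = 20,
    min_size: int = 8,
    max_size: int = 40,
) -> pd.DataFrame:
    """Random pathway catalog over the simulated genes (pathway_id, name,
    gene_id). Every gene is guaranteed >= 1 pathway so the catalog's
    universe covers the annotation."""
    rng = config.rng(_STREAM_CATALOG)
    gene_ids = [g.gene_id for g in annotation]
    rows = []
    for i in range(n_pathways):
        size = int(rng.integers(min_size, max_size + 1))
        members = rng.choice(len(gene_ids), size=min(size, len(gene_ids)), replace=False)
        for m in members:
            rows.append(
                {"pathway_id": f"path{i:03d}", "name": f"synthetic pathway {i}",
                 "gene_id": gene_ids[int(m)]}
            )
    covered = {r["gene_id"] for r in rows}
    for gid in gene_ids:
        if gid not in covered:
            pid = int(rng.integers(0, n_pathways))
            rows.append(
                {"pathway_id": f"path{pid:03d}", "name": f"synthetic pathway {pid}",
                 "gene_id": gid}
            )
    return pd.DataFrame(rows, columns=["pathway_id", "name", "gene_id"])


def make_decoy_pwms(
    n: int,
    length: int = 12,
    seed: int | np.random.Generator = 0,
    sharpness: float = 8.0,
) -> list[PWM]:
    """Generate decoy motif matrices with Dirichlet-sharpened columns.

    Decoys have realistic information content (one dominant base per
    position) but random identity, so they exercise scanner thresholds
    without matching planted instances.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng([int(seed), _STREAM_DECOYS])
    out = []
    for i in range(n):
        counts = np.ones((length, 4))
        for j in range(length):
            dominant = rng.integers(0, 4)
            alpha = np.ones(4)
            alpha[dominant] = sharpness
            counts[j] = np.round(rng.dirichlet(alpha) * 100) + 1
        out.append(PWM(matrix_id=f"V$DECOY_{i:02d}", factor_name=f"decoy{i}", counts=counts))
    return out
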