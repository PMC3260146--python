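"""MATCH-style PWM scanning and motif enrichment against a matched background.

The scanner implements the MATCH similarity scores: position weights
``I(i) = sum_b f(i,b) ln(4 f(i,b))`` (the information vector), a matrix
similarity normalized between the matrix's minimum and maximum attainable
weighted scores, and a core similarity computed identically over the five
consecutive positions with the largest total information. A window is a hit
iff both similarities reach their per-matrix thresholds; windows containing
``N`` never hit, and both strands are scanned.

Enrichment compares, per PWM, the proportion of nucleotides covered by a
hit in the true binding sites (``p_t``) against the same proportion in
length-matched background sites drawn from each site's vicinity (``p_b``),
with a pooled two-proportion z statistic and Bonferroni correction across
the library. Strongly negative z (depletion) is as reportable as
enrichment, so p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .formats import BASES, GenomicInterval, PWM

__all__ = [
    "MotifHit",
    "EnrichmentResult",
    "ConsensusMotif",
    "information_vector",
    "match_scan",
    "scan_sites",
    "generate_background",
    "extract_sequences",
    "coverage_proportion",
    "enrichment_z",
    "enrich_all",
    "enrichment_table",
    "pre_hit_rule",
    "build_consensus",
    "format_pvalue",
    "PR_MATRIX_IDS",
]

CORE_LENGTH = 5
DEFAULT_PSEUDOCOUNT = 0.01
PR_MATRIX_IDS = ("V$PR_01", "V$PR_02", "V$PR_Q2")

#: smallest positive float; p-values below the printable range are floored
#: here and rendered as "<1.0e-323"
P_FLOOR = np.nextafter(0.0, 1.0)

_CODE = np.full(256, 4, dtype=np.int8)  # everything unknown scans as N
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One scanner hit. ``offset`` indexes the leftmost base of the matched
    window within the site, in forward-strand coordinates; ``matched_seq``
    is the forward-strand genomic subsequence (reverse-complement it to get
    the motif-oriented sequence of a ``-`` strand hit)."""

    site_id: str
    offset: int
    strand: str
    core_score: float
    matrix_score: float
    matched_seq: str


@dataclass
class EnrichmentResult:
    matrix_id: str
    factor_name: str
    p_t: float
    p_b: float
    n: int
    z: float
    p_raw: float
    p_bonf: float
    n_sites_with_hit: int


@dataclass
class ConsensusMotif:
    """Per-position base frequencies with a dominance-threshold consensus
    string over {A, C, G, T, •}."""

    frequencies: np.ndarray  # (L, 4)
    consensus: str
    n_sequences: int

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]


def information_vector(
    pwm: PWM, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """Per-position information weight I(i) = sum_b f(i,b) ln(4 f(i,b)),
    with 0 ln 0 taken as 0; ranges from 0 (uniform) to ln 4 (one-hot)."""
    f = pwm.frequencies(pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return term.sum(axis=1)


class _CompiledPWM:
    """Pre-computed scanning tables for one PWM orientation."""

    def __init__(self, f: np.ndarray, core_thr: float, matrix_thr: float):
        with np.errstate(divide="ignore", invalid="ignore"):
            info = np.where(f > 0, f * np.log(4.0 * f), 0.0).sum(axis=1)
        self.L = f.shape[0]
        W = info[:, None] * f  # (L, 4) weighted frequencies
        # 5th column: N contributes the column minimum, and the window is
        # masked out separately anyway
        self.W5 = np.column_stack([W, W.min(axis=1)])
        self.min_total = W.min(axis=1).sum()
        self.max_total = W.max(axis=1).sum()
        self.degenerate = not (self.max_total > self.min_total)
        # core = CORE_LENGTH consecutive positions maximizing total info
        if self.L <= CORE_LENGTH:
            c0, c1 = 0, self.L
        else:
            sums = np.convolve(info, np.ones(CORE_LENGTH), mode="valid")
            c0 = int(np.argmax(sums))
            c1 = c0 + CORE_LENGTH
        self.core = (c0, c1)
        self.core_min = W[c0:c1].min(axis=1).sum()
        self.core_max = W[c0:c1].max(axis=1).sum()
        self.core_degenerate = not (self.core_max > self.core_min)
        self.core_thr = core_thr
        self.matrix_thr = matrix_thr

    def scan_codes(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (positions, matrix_scores, core_scores) of hits over an
        integer-coded sequence (A=0..T=3, N=4)."""
        L, M = self.L, codes.shape[0]
        if M < L or self.degenerate or self.core_degenerate:
            return np.empty(0, dtype=int), np.empty(0), np.empty(0)
        n_win = M - L + 1
        current = np.zeros(n_win)
        for i in range(L):
            current += self.W5[i, codes[i:i + n_win]]
        matrix = (current - self.min_total) / (self.max_total - self.min_total)
        # windows containing N never hit
        is_n = (codes == 4).astype(np.int64)
        cn = np.concatenate([[0], np.cumsum(is_n)])
        clean = (cn[L:] - cn[:-L]) == 0
        cand = np.nonzero(clean & (matrix >= self.matrix_thr))[0]
        if cand.size == 0:
            return cand, np.empty(0), np.empty(0)
        # core similarity only where the matrix score already qualifies
        c0, c1 = self.core
        core_cur = np.zeros(cand.size)
        for i in range(c0, c1):
            core_cur += self.W5[i, codes[cand + i]]
        core = (core_cur - self.core_min) / (self.core_max - self.core_min)
        keep = core >= self.core_thr
        pos = cand[keep]
        return pos, matrix[pos], core[keep]


def _compile_both(pwm: PWM, pseudocount: float) -> tuple[_CompiledPWM, _CompiledPWM]:
    f = pwm.frequencies(pseudocount)
    fwd = _CompiledPWM(f, pwm.core_threshold, pwm.matrix_threshold)
    # reverse complement: reverse positions, swap A<->T and C<->G
    rev = _CompiledPWM(f[::-1, ::-1], pwm.core_threshold, pwm.matrix_threshold)
    if fwd.degenerate:
        warnings.warn(f"{pwm.matrix_id}: degenerate matrix (max == min), no hits")
    return fwd, rev


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def match_scan(
    sequence: str,
    pwm: PWM,
    site_id: str = ".",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[MotifHit]:
    """Scan one sequence with one PWM on both strands."""
    return scan_sites([sequence], pwm, [site_id], pseudocount=pseudocount)


def scan_sites(
    sequences: Sequence[str],
    pwm: PWM,
    site_ids: Sequence[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[MotifHit]:
    """Scan many site sequences with one PWM.

    Sequences are concatenated with ``N`` spacers and scanned in one pass
    per strand; spacer-straddling windows are excluded by the N rule.
    """
    if site_ids is None:
        site_ids = [f"s{i}" for i in range(len(sequences))]
    fwd, rev = _compile_both(pwm, pseudocount)
    L = len(pwm)
    sep = "N" * L
    concat = sep.join(sequences)
    codes = _encode(concat)
    starts = np.empty(len(sequences), dtype=np.int64)
    off = 0
    for i, s in enumerate(sequences):
        starts[i] = off
        off += len(s) + L
    hits: list[MotifHit] = []
    for comp, strand in ((fwd, "+"), (rev, "-")):
        pos, matrix, core = comp.scan_codes(codes)
        if pos.size == 0:
            continue
        site_idx = np.searchsorted(starts, pos, side="right") - 1
        for p, si, m, c in zip(pos, site_idx, matrix, core):
            local = int(p - starts[si])
            hits.append(
                MotifHit(
                    site_id=site_ids[int(si)],
                    offset=local,
                    strand=strand,
                    core_score=float(c),
                    matrix_score=float(m),
                    matched_seq=sequences[int(si)][local:local + L],
                )
            )
    hits.sort(key=lambda h: (h.site_id, h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Background construction

def generate_background(
    sites: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    min_shift: int = 1000,
    max_shift: int = 10_000,
    seed: int | np.random.Generator = 0,
    max_tries: int = 100,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Draw one length-matched background interval from each site's vicinity.

    The shift magnitude is uniform in [min_shift, max_shift] with random
    direction; a candidate is redrawn if it leaves the chromosome or
    overlaps ANY true site. A site with no valid placement after
    ``max_tries`` draws is dropped from both sets, keeping the true and
    background groups the same size.

    Returns ``(kept_true_sites, background_sites)`` in matching order.
    """
    if not (0 < min_shift < max_shift):
        raise ValueError("require 0 < min_shift < max_shift")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end)
    kept, background = [], []
    for s in sites:
        clen = chrom_sizes[s.chrom]
        placed = None
        for _ in range(max_tries):
            shift = int(rng.integers(min_shift, max_shift + 1))
            if rng.random() < 0.5:
                shift = -shift
            start = s.start + shift
            if start < 0 or start + s.length > clen:
                continue
            if trees[s.chrom].overlap(start, start + s.length):
                continue
            placed = GenomicInterval(s.chrom, start, start + s.length,
                                     id=f"bg_{s.id}")
            break
        if placed is None:
            warnings.warn(f"{s.id}: no valid background placement, site excluded")
            continue
        kept.append(s)
        background.append(placed)
    return kept, background


def extract_sequences(
    sites: Sequence[GenomicInterval], genome: Mapping[str, str]
) -> list[str]:
    return [genome[s.chrom][s.start:s.end] for s in sites]


# ---------------------------------------------------------------------------
# Enrichment statistic

def coverage_proportion(
    hits: Iterable[MotifHit], sites: Sequence[GenomicInterval], motif_length: int
) -> tuple[float, int]:
    """Proportion of site nucleotides covered by >= 1 hit footprint.

    Footprints from both strands project onto the same nucleotides and
    overlapping footprints are counted once (union semantics). Returns
    ``(proportion, n_sites_with_hit)``.
    """
    total = sum(s.length for s in sites)
    if total == 0:
        return 0.0, 0
    by_site: dict[str, list[int]] = {}
    for h in hits:
        by_site.setdefault(h.site_id, []).append(h.offset)
    lengths = {s.id: s.length for s in sites}
    covered = 0
    for sid, offsets in by_site.items():
        offsets.sort()
        site_len = lengths[sid]
        cur_a = cur_b = -1
        for off in offsets:
            a, b = off, min(off + motif_length, site_len)
            if a <= cur_b:
                cur_b = max(cur_b, b)
            else:
                covered += max(0, cur_b - cur_a)
                cur_a, cur_b = a, b
        covered += max(0, cur_b - cur_a)
    return covered / total, len(by_site)


def enrichment_z(p_t: float, p_b: float, n: int) -> tuple[float, float]:
    """Pooled two-proportion z statistic with equal group sizes ``n``.

    z = (p_t - p_b) / sqrt(pbar (1 - pbar) * 2 / n) with
    pbar = (p_t + p_b) / 2; the p-value is the two-sided normal tail,
    floored at the smallest positive float. When pbar is 0 or 1 the
    statistic is undefined and the result is flagged non-significant
    (z = nan, p = 1).
    """
    if not (0.0 <= p_t <= 1.0 and 0.0 <= p_b <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    pbar = 0.5 * (p_t + p_b)
    if pbar <= 0.0 or pbar >= 1.0:
        return float("nan"), 1.0
    z = (p_t - p_b) / np.sqrt(pbar * (1.0 - pbar) * 2.0 / n)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(max(p, P_FLOOR))


def format_pvalue(p: float) -> str:
    """Render a p-value, using the '<1.0e-323' convention below the
    printable floating-point range."""
    if p < 1.0e-323:
        return "<1.0e-323"
    return f"{p:.1e}"


def enrich_all(
    pwm_library: Sequence[PWM],
    true_sites: Sequence[GenomicInterval],
    background_sites: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[EnrichmentResult]:
    """Per-PWM enrichment of true vs background sites, Bonferroni-corrected
    over the library and sorted by corrected p (ties by |z| descending)."""
    if not pwm_library:
        raise ValueError("empty PWM library")
    if len(true_sites) != len(background_sites):
        raise ValueError(
            f"true ({len(true_sites)}) and background ({len(background_sites)}) "
            "site counts must be equal"
        )
    true_seqs = extract_sequences(true_sites, genome)
    bg_seqs = extract_sequences(background_sites, genome)
    true_ids = [s.id for s in true_sites]
    bg_ids = [s.id for s in background_sites]
    n = sum(s.length for s in true_sites)
    m = len(pwm_library)
    results = []
    for pwm in pwm_library:
        hits_t = scan_sites(true_seqs, pwm, true_ids, pseudocount)
        hits_b = scan_sites(bg_seqs, pwm, bg_ids, pseudocount)
        p_t, n_with = coverage_proportion(hits_t, true_sites, len(pwm))
        p_b, _ = coverage_proportion(hits_b, background_sites, len(pwm))
        z, p_raw = enrichment_z(p_t, p_b, n)
        results.append(
            EnrichmentResult(
                matrix_id=pwm.matrix_id,
                factor_name=pwm.factor_name,
                p_t=p_t,
                p_b=p_b,
                n=n,
                z=z,
                p_raw=p_raw,
                p_bonf=min(1.0, p_raw * m),
                n_sites_with_hit=n_with,
            )
        )
    results.sort(key=lambda r: (r.p_bonf, -abs(r.z) if np.isfinite(r.z) else 0.0))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "factor": r.factor_name,
                "matrix_id": r.matrix_id,
                "p_t": r.p_t,
                "p_b": r.p_b,
                "n": r.n,
                "z": r.z,
                "p_raw": format_pvalue(r.p_raw),
                "p_bonf": format_pvalue(r.p_bonf),
                "n_sites_with_hit": r.n_sites_with_hit,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# PRE triad rule and consensus

def pre_hit_rule(
    hits_by_matrix: Mapping[str, Iterable[MotifHit]],
    site_ids: Sequence[str],
    pr_matrix_ids: Sequence[str] = PR_MATRIX_IDS,
) -> tuple[dict[str, bool], pd.DataFrame]:
    """A site carries a PR motif if any of the PR matrices hit it at least
    once (logical OR over the triad).

    Returns the per-site flags and a table of per-matrix site counts with
    percentages to one decimal, plus a combined "any PR matrix" row.
    """
    total = len(site_ids)
    sites_per_matrix = {
        mid: {h.site_id for h in hits_by_matrix.get(mid, [])} for mid in pr_matrix_ids
    }
    any_pr = set().union(*sites_per_matrix.values()) if sites_per_matrix else set()
    flags = {sid: sid in any_pr for sid in site_ids}
    rows = [
        {
            "matrix_id": mid,
            "n_sites_with_motif": len(sites_per_matrix[mid]),
            "percent": round(100.0 * len(sites_per_matrix[mid]) / total, 1) if total else 0.0,
        }
        for mid in pr_matrix_ids
    ]
    rows.append(
        {
            "matrix_id": "any",
            "n_sites_with_motif": len(any_pr),
            "percent": round(100.0 * len(any_pr) / total, 1) if total else 0.0,
        }
    )
    return flags, pd.DataFrame(rows)


def build_consensus(
    hits: Sequence[MotifHit], dominance_threshold: float = 0.5
) -> ConsensusMotif:
    """Stack matched sequences (reverse-complementing ``-`` strand hits into
    motif orientation) and call a consensus letter wherever the modal base
    frequency strictly exceeds the dominance threshold; '•' elsewhere."""
    if len(hits) < 2:
        raise ValueError("need >= 2 hits to build a consensus")
    seqs = [
        revcomp(h.matched_seq) if h.strand == "-" else h.matched_seq for h in hits
    ]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"hits of unequal length: {sorted(lengths)}")
    L = lengths.pop()
    counts = np.zeros((L, 4))
    for s in seqs:
        codes = _encode(s)
        for i, c in enumerate(codes):
            if c < 4:
                counts[i, c] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs = counts / totals
    letters = []
    for i in range(L):
        j = int(freqs[i].argmax())
        letters.append(BASES[j] if freqs[i, j] > dominance_threshold else "•")
    return ConsensusMotif(frequencies=freqs, consensus="".join(letters),
                          n_sequences=len(seqs))
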