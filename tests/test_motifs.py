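import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_sequence
from prbind.formats import PWM, GenomicInterval
from prbind.motifs import (
    CORE_LENGTH,
    MotifHit,
    build_consensus,
    coverage_proportion,
    enrich_all,
    enrichment_z,
    format_pvalue,
    generate_background,
    information_vector,
    match_scan,
    pre_hit_rule,
    revcomp,
    scan_sites,
)
from prbind.simdata import SimConfig, make_decoy_pwms, sample_pwm_instance


def naive_match_scores(seq: str, pwm: PWM, pseudocount: float = 0.01):
    """Position-by-position direct recomputation of the MATCH similarities
    for the forward orientation of one matrix; independent of the scanner."""
    f = (pwm.counts + pseudocount)
    f = f / f.sum(axis=1, keepdims=True)
    L = len(pwm)
    info = [sum(f[i][b] * math.log(4 * f[i][b]) for b in range(4)) for i in range(L)]
    # core window = CORE_LENGTH consecutive positions with max total info
    if L <= CORE_LENGTH:
        c0, c1 = 0, L
    else:
        sums = [sum(info[i:i + CORE_LENGTH]) for i in range(L - CORE_LENGTH + 1)]
        c0 = int(np.argmax(sums))
        c1 = c0 + CORE_LENGTH
    idx = {b: i for i, b in enumerate("ACGT")}
    lo = sum(info[i] * min(f[i]) for i in range(L))
    hi = sum(info[i] * max(f[i]) for i in range(L))
    clo = sum(info[i] * min(f[i]) for i in range(c0, c1))
    chi = sum(info[i] * max(f[i]) for i in range(c0, c1))
    out = []
    for p in range(len(seq) - L + 1):
        win = seq[p:p + L]
        if "N" in win:
            continue
        cur = sum(info[i] * f[i][idx[win[i]]] for i in range(L))
        ccur = sum(info[i] * f[i][idx[win[i]]] for i in range(c0, c1))
        out.append((p, (cur - lo) / (hi - lo), (ccur - clo) / (chi - clo)))
    return out


class TestInformationVector:
    def test_one_hot_column_is_ln4(self):
        p = PWM("V$X", "x", np.array([[1, 0, 0, 0]]), 0.9, 0.85)
        assert information_vector(p, pseudocount=0.0)[0] == pytest.approx(math.log(4))

    def test_uniform_column_is_zero(self):
        p = PWM("V$X", "x", np.array([[1, 1, 1, 1]]))
        assert information_vector(p, pseudocount=0.0)[0] == pytest.approx(0.0)

    def test_half_half_column_is_ln2(self):
        p = PWM("V$X", "x", np.array([[1, 1, 0, 0]]))
        assert information_vector(p, pseudocount=0.0)[0] == pytest.approx(math.log(2))

    def test_range_with_pseudocount(self, pr01):
        iv = information_vector(pr01)
        assert (iv >= 0).all() and (iv <= math.log(4) + 1e-12).all()


class TestMatchScan:
    def test_consensus_sequence_scores_one(self, pr01):
        seq = pr01.consensus()
        hits = [h for h in match_scan(seq, pr01) if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].matrix_score == pytest.approx(1.0)
        assert hits[0].core_score == pytest.approx(1.0)

    def test_reverse_complement_hit_on_minus_strand(self, pr01):
        seq = revcomp(pr01.consensus())
        hits = [h for h in match_scan(seq, pr01) if h.strand == "-"]
        assert len(hits) == 1
        assert hits[0].matrix_score == pytest.approx(1.0)
        assert revcomp(hits[0].matched_seq) == pr01.consensus()

    def test_strand_symmetry_on_random_sequence(self, pr01, rng):
        seq = random_sequence(rng, 3000)
        fwd = match_scan(seq, pr01, "s")
        rc = match_scan(revcomp(seq), pr01, "s")
        L = len(pr01)
        mirrored = sorted(
            (len(seq) - h.offset - L, {"+": "-", "-": "+"}[h.strand],
             round(h.matrix_score, 9))
            for h in rc
        )
        assert mirrored == sorted(
            (h.offset, h.strand, round(h.matrix_score, 9)) for h in fwd
        )

    def test_windows_with_n_never_hit(self, pr01):
        seq = pr01.consensus()
        assert match_scan(seq[:6] + "N" + seq[7:], pr01) == []

    def test_matches_naive_recomputation(self, pr01, rng):
        # 10 kb random sequence: identical hit set to the direct-formula scan
        seq = random_sequence(rng, 10_000)
        # lenient thresholds so the comparison covers many hits
        pwm = PWM(pr01.matrix_id, pr01.factor_name, pr01.counts, 0.6, 0.5)
        got = {(h.offset, round(h.matrix_score, 10), round(h.core_score, 10))
               for h in match_scan(seq, pwm) if h.strand == "+"}
        expected = {
            (p, round(m, 10), round(c, 10))
            for p, m, c in naive_match_scores(seq, pwm)
            if m >= 0.5 and c >= 0.6
        }
        assert got == expected

    def test_degenerate_matrix_warns_and_yields_nothing(self):
        p = PWM("V$U", "u", np.array([[1, 1, 1, 1]] * 6))
        with pytest.warns(UserWarning, match="degenerate"):
            assert match_scan("ACGTACGTACGT", p) == []

    def test_hit_scores_respect_thresholds(self, pre_library, rng):
        seq = random_sequence(rng, 20_000)
        for pwm in pre_library:
            for h in match_scan(seq, pwm):
                assert h.matrix_score >= pwm.matrix_threshold
                assert h.core_score >= pwm.core_threshold
                assert h.offset + len(pwm) <= len(seq)


class TestBackground:
    def _sites(self, n, rng, chrom_len=10_000_000, length=1000):
        starts = np.sort(rng.choice(chrom_len // (2 * length), size=n, replace=False))
        return [
            GenomicInterval("chr1", int(a) * 2 * length, int(a) * 2 * length + length,
                            id=f"s{i}")
            for i, a in enumerate(starts)
        ]

    def test_all_placed_with_valid_shifts(self, rng):
        sites = self._sites(1000, rng)
        kept, background = generate_background(sites, {"chr1": 10_000_000}, seed=rng)
        assert len(kept) == len(background) == 1000
        truth = {(s.start, s.end) for s in sites}
        for s, b in zip(kept, background):
            shift = abs(b.start - s.start)
            assert 1000 <= shift <= 10_000
            assert b.length == s.length
            assert all(not (b.start < e and b.end > a) for a, e in truth)

    def test_background_never_overlaps_true_sites(self, rng):
        sites = self._sites(200, rng, chrom_len=1_000_000)
        kept, background = generate_background(sites, {"chr1": 1_000_000}, seed=rng)
        from intervaltree import IntervalTree

        tree = IntervalTree()
        for s in sites:
            tree.addi(s.start, s.end)
        assert all(not tree.overlap(b.start, b.end) for b in background)

    def test_unplaceable_site_dropped_from_both_sets(self):
        # one site covering nearly the whole chromosome leaves no room
        crowded = GenomicInterval("chr1", 1000, 2000, id="a")
        sizes = {"chr1": 3000}
        with pytest.warns(UserWarning, match="no valid background"):
            kept, background = generate_background([crowded], sizes, seed=0)
        assert kept == [] and background == []

    def test_invalid_shift_range_rejected(self):
        with pytest.raises(ValueError):
            generate_background([], {}, min_shift=500, max_shift=500)


class TestCoverage:
    def _site(self, length=1000):
        return GenomicInterval("chr1", 0, length, id="s1")

    def test_no_hits_zero(self):
        assert coverage_proportion([], [self._site()], 13) == (0.0, 0)

    def test_single_13nt_hit(self):
        h = MotifHit("s1", 100, "+", 1.0, 1.0, "A" * 13)
        p, n = coverage_proportion([h], [self._site()], 13)
        assert p == pytest.approx(0.013)
        assert n == 1

    def test_overlapping_hits_union(self):
        hits = [
            MotifHit("s1", 10, "+", 1, 1, "A" * 13),  # covers 10-22
            MotifHit("s1", 15, "-", 1, 1, "A" * 13),  # covers 15-27
        ]
        p, _ = coverage_proportion(hits, [self._site()], 13)
        assert p == pytest.approx(18 / 1000)


class TestEnrichmentZ:
    def test_equal_proportions_zero(self):
        z, p = enrichment_z(0.3, 0.3, 1000)
        assert z == 0.0 and p == 1.0

    def test_pooled_value_matches_independent_oracle(self):
        z, p = enrichment_z(0.3, 0.2, 1000)
        assert z == pytest.approx(5.164, abs=5e-3)
        # statsmodels' pooled two-proportion z on the equivalent counts
        from statsmodels.stats.proportion import proportions_ztest

        z_sm, p_sm = proportions_ztest([300, 200], [1000, 1000])
        assert z == pytest.approx(z_sm, rel=1e-12)
        assert p == pytest.approx(p_sm, rel=1e-12)

    def test_depletion_is_negative(self):
        z, _ = enrichment_z(0.1, 0.2, 1000)
        assert z < 0

    def test_degenerate_pooled_proportion_flagged(self):
        z, p = enrichment_z(0.0, 0.0, 1000)
        assert math.isnan(z) and p == 1.0
        z, p = enrichment_z(1.0, 1.0, 1000)
        assert math.isnan(z) and p == 1.0

    def test_p_floor(self):
        z, p = enrichment_z(0.9, 0.0001, 10_000_000)
        assert p > 0
        assert format_pvalue(p) == "<1.0e-323"

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.floats(0.001, 0.999), st.floats(0.001, 0.999), st.integers(10, 10**6)
    )
    def test_sign_matches_difference(self, pt, pb, n):
        z, p = enrichment_z(pt, pb, n)
        assert np.sign(z) == np.sign(pt - pb)
        assert 0 < p <= 1


class TestEnrichAll:
    def _landscape(self, seed=11, n_sites=60, chrom_len=3_000_000, plant=0.4):
        from prbind import simdata

        cfg = SimConfig(
            chrom_lengths={"chr1": chrom_len}, n_genes=50, n_sites=n_sites,
            plant_rate_true=plant, linked_fraction=0.0, seed=seed,
        )
        genome = simdata.simulate_genome(cfg)
        genes = simdata.simulate_annotation(cfg, genome)
        from prbind.formats import parse_transfac
        from prbind.pipeline import default_matrix_path

        pr01 = next(p for p in parse_transfac(default_matrix_path())
                    if p.matrix_id == "V$PR_01")
        genome, sites, truth = simdata.plant_sites(cfg, genome, genes, pr01)
        return genome, sites, pr01

    def test_planted_pwm_ranks_first_among_decoys(self):
        # 500 sites with a 30% plant rate: the planted matrix must dominate
        genome, sites, pr01 = self._landscape(n_sites=500, chrom_len=15_000_000,
                                              plant=0.3)
        kept, background = generate_background(
            sites, {c: len(s) for c, s in genome.items()}, seed=3
        )
        library = [pr01] + make_decoy_pwms(10, seed=3)
        results = enrich_all(library, kept, background, genome)
        assert results[0].matrix_id == "V$PR_01"
        assert results[0].z > 0

    def test_single_pwm_bonferroni_identity(self, pr01, rng):
        genome = {"chr1": random_sequence(rng, 1_300_000)}
        sites = [GenomicInterval("chr1", i * 25_000, i * 25_000 + 1000, id=f"s{i}")
                 for i in range(50)]
        kept, background = generate_background(sites, {"chr1": 1_300_000}, seed=1)
        (res,) = enrich_all([pr01], kept, background, genome)
        assert res.p_bonf == pytest.approx(res.p_raw)

    def test_identical_sequences_give_zero_z(self, pr01):
        # same sequence content in both groups: proportions equal
        block = (pr01.consensus() + "ACGTACGT" * 10)[:80]
        genome = {"chr1": block * 100}
        sites = [GenomicInterval("chr1", 0, 800, id="t1")]
        bg = [GenomicInterval("chr1", 1600, 2400, id="b1")]
        (res,) = enrich_all([pr01], sites, bg, genome)
        assert res.z == 0.0 and res.p_raw == 1.0

    def test_bonferroni_bounds(self):
        genome, sites, pr01 = self._landscape(seed=5, n_sites=40)
        kept, background = generate_background(
            sites, {c: len(s) for c, s in genome.items()}, seed=7
        )
        results = enrich_all([pr01] + make_decoy_pwms(5, seed=7), kept, background, genome)
        for r in results:
            assert r.p_bonf >= r.p_raw
            assert r.p_bonf <= 1.0

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enrich_all([], [], [], {})

    def test_unequal_group_sizes_rejected(self, pr01):
        s = GenomicInterval("chr1", 0, 10)
        with pytest.raises(ValueError, match="equal"):
            enrich_all([pr01], [s], [], {"chr1": "ACGT" * 10})


class TestPreRule:
    def _hit(self, sid, mid="V$PR_Q2"):
        return MotifHit(sid, 0, "+", 1, 1, "TGTTCT")

    def test_any_single_matrix_suffices(self):
        flags, table = pre_hit_rule(
            {"V$PR_Q2": [self._hit("s1")]}, ["s1", "s2"]
        )
        assert flags == {"s1": True, "s2": False}

    def test_counts_and_percentages(self):
        hits = {"V$PR_01": [self._hit(f"s{i}") for i in range(124)]}
        site_ids = [f"s{i}" for i in range(7034)]
        flags, table = pre_hit_rule(hits, site_ids)
        row = table[table["matrix_id"] == "V$PR_01"].iloc[0]
        assert row["n_sites_with_motif"] == 124
        assert row["percent"] == 1.8

    def test_no_hits_all_negative(self):
        flags, table = pre_hit_rule({}, ["s1"])
        assert flags == {"s1": False}
        assert (table["n_sites_with_motif"] == 0).all()


class TestConsensus:
    def test_unanimous_hits(self):
        hits = [MotifHit("s", 0, "+", 1, 1, "GAACA") for _ in range(5)]
        assert build_consensus(hits).consensus == "GAACA"

    def test_exact_half_frequency_is_dot(self):
        hits = [
            MotifHit("s", 0, "+", 1, 1, "A"),
            MotifHit("s", 0, "+", 1, 1, "A"),
            MotifHit("s", 0, "+", 1, 1, "C"),
            MotifHit("s", 0, "+", 1, 1, "G"),
        ]
        assert build_consensus(hits).consensus == "•"  # 0.5 not > 0.5

    def test_minus_strand_reverse_complemented(self):
        hits = [
            MotifHit("s", 0, "+", 1, 1, "GAACA"),
            MotifHit("s", 0, "-", 1, 1, revcomp("GAACA")),
        ]
        assert build_consensus(hits).consensus == "GAACA"

    def test_unequal_lengths_rejected(self):
        hits = [
            MotifHit("s", 0, "+", 1, 1, "GAACA"),
            MotifHit("s", 0, "+", 1, 1, "GAAC"),
        ]
        with pytest.raises(ValueError, match="unequal"):
            build_consensus(hits)

    def test_fewer_than_two_hits_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([MotifHit("s", 0, "+", 1, 1, "GAACA")])

    def test_sampled_hits_recover_planted_frame(self, pr01):
        rng = np.random.default_rng(99)
        hits = [
            MotifHit("s", 0, "+", 1, 1, sample_pwm_instance(pr01, rng))
            for _ in range(500)
        ]
        cons = build_consensus(hits, 0.5)
        assert cons.consensus == "G•ACA•••TGT•C"


class TestScanSites:
    def test_concatenated_scan_equals_per_site(self, pr01, rng):
        seqs = [random_sequence(rng, 500) for _ in range(20)]
        pwm = PWM(pr01.matrix_id, pr01.factor_name, pr01.counts, 0.5, 0.4)
        combined = scan_sites(seqs, pwm, [f"s{i}" for i in range(20)])
        separate = []
        for i, s in enumerate(seqs):
            separate += match_scan(s, pwm, f"s{i}")
        key = lambda h: (h.site_id, h.offset, h.strand)
        assert sorted(combined, key=key) == sorted(separate, key=key)
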