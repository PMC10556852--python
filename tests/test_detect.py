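"""Consecutive-runs and sliding-window ROH callers against brute-force oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rohscan import (
    ConsecutiveParams,
    SlidingParams,
    detect_consecutive,
    detect_sliding,
    get_preset,
    snp_window_support,
)

from conftest import (
    E,
    H,
    M,
    brute_force_homozygous_runs,
    brute_force_window_support,
    make_gm,
    random_chromosome,
)


def _spans(segments):
    return [(s.start_bp, s.end_bp, s.n_snp) for s in segments]


class TestDetectConsecutive:
    def test_single_maximal_run(self):
        """25 homozygous SNPs over 2.4 Mb give exactly one segment."""
        gm = make_gm([H] * 25)  # 100 kb spacing -> 2.4 Mb span
        segs = detect_consecutive(gm, ConsecutiveParams(min_snp=20))
        assert len(segs) == 1
        (seg,) = segs
        assert (seg.n_snp, seg.n_het, seg.n_missing) == (25, 0, 0)
        assert seg.length_bp == 2_400_000

    def test_all_het_yields_nothing(self):
        gm = make_gm([E] * 50)
        for max_het in (0, 1, 2):
            assert detect_consecutive(gm, ConsecutiveParams(min_snp=2, max_het=max_het)) == []

    @pytest.mark.parametrize(
        "max_het,min_snp,expected_n_snp",
        [(0, 20, [20, 20]), (0, 15, [20, 20]), (1, 20, [41])],
    )
    def test_het_budget_splits_or_bridges(self, max_het, min_snp, expected_n_snp):
        """41 calls with one HET at index 20: budget 0 splits into two 20-SNP
        runs, budget 1 bridges into one 41-SNP run containing the het."""
        calls = [H] * 41
        calls[20] = E
        gm = make_gm(calls)
        segs = detect_consecutive(
            gm, ConsecutiveParams(min_snp=min_snp, max_het=max_het, max_missing=0))
        assert [s.n_snp for s in segs] == expected_n_snp
        assert sum(s.n_het for s in segs) == (1 if max_het == 1 else 0)

    def test_min_snp_drops_short_runs(self):
        calls = [H] * 41
        calls[20] = E
        gm = make_gm(calls)
        segs = detect_consecutive(gm, ConsecutiveParams(min_snp=21, max_het=0))
        assert segs == []

    def test_gap_splits_runs(self):
        """Two 30-SNP homozygous blocks separated by a 1.5 Mb gap split at
        max_gap 1 Mb."""
        pos = np.concatenate([
            (np.arange(30) + 1) * 100_000,
            3_000_000 + 1_500_000 + np.arange(30) * 100_000,
        ])
        gm = make_gm([H] * 60, pos=pos)
        segs = detect_consecutive(gm, ConsecutiveParams(min_snp=20))
        assert len(segs) == 2
        assert all(s.n_snp == 30 for s in segs)
        merged = detect_consecutive(
            gm, ConsecutiveParams(min_snp=20, max_gap_bp=2_000_000))
        assert len(merged) == 1 and merged[0].n_snp == 60

    def test_missing_budget(self):
        """A missing call splits at budget 0 and is bridged (counted in n_snp
        and n_missing, never n_het) at budget 1."""
        calls = [H] * 30
        calls[15] = M
        gm = make_gm(calls)
        assert len(detect_consecutive(gm, ConsecutiveParams(min_snp=10))) == 2
        segs = detect_consecutive(gm, ConsecutiveParams(min_snp=10, max_missing=1))
        assert len(segs) == 1
        assert (segs[0].n_snp, segs[0].n_het, segs[0].n_missing) == (30, 0, 1)

    def test_unsorted_map_rejected(self):
        gm = make_gm([H] * 5, pos=[100, 300, 200, 400, 500])
        with pytest.raises(ValueError, match="not strictly increasing"):
            detect_consecutive(gm, ConsecutiveParams(min_snp=2))

    def test_oracle_equivalence_zero_budgets(self):
        """At het/missing budgets 0, output equals the brute-force maximal
        all-homozygous-stretch enumerator on random small chromosomes."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            pos, calls = random_chromosome(rng)
            min_snp = int(rng.integers(2, 8))
            min_len = int(rng.integers(0, 500_000))
            max_gap = int(rng.integers(500_000, 2_000_000))
            gm = make_gm(calls, pos=pos)
            p = ConsecutiveParams(min_snp=min_snp, min_length_bp=min_len,
                                  max_gap_bp=max_gap)
            got = [(s.start_bp, s.end_bp) for s in detect_consecutive(gm, p)]
            want = [(int(pos[a]), int(pos[b]))
                    for a, b in brute_force_homozygous_runs(
                        pos, calls, min_snp, min_len, max_gap)]
            assert got == want

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_emitted_segments_respect_budgets(self, seed):
        """Every emitted segment honours its own parameter budgets."""
        rng = np.random.default_rng(seed)
        pos, calls = random_chromosome(rng)
        p = ConsecutiveParams(
            min_snp=int(rng.integers(2, 6)),
            max_het=int(rng.integers(0, 3)),
            max_missing=int(rng.integers(0, 5)),
            min_length_bp=int(rng.integers(0, 400_000)),
        )
        for s in detect_consecutive(make_gm(calls, pos=pos), p):
            assert s.n_het <= p.max_het
            assert s.n_missing <= p.max_missing
            assert s.n_snp >= p.min_snp
            assert s.length_bp >= p.min_length_bp

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_coverage_monotone_in_budgets(self, seed):
        """Total ROH bp-coverage never shrinks as het or missing budgets grow."""
        rng = np.random.default_rng(seed)
        pos, calls = random_chromosome(rng)
        gm = make_gm(calls, pos=pos)

        def coverage(max_het, max_missing):
            segs = detect_consecutive(gm, ConsecutiveParams(
                min_snp=2, max_het=max_het, max_missing=max_missing,
                min_length_bp=0))
            return sum(s.length_bp for s in segs)

        for h in (0, 1):
            assert coverage(h + 1, 0) >= coverage(h, 0)
        for m in (0, 1, 2, 3):
            assert coverage(0, m + 1) >= coverage(0, m)

    def test_segments_non_overlapping(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pos, calls = random_chromosome(rng)
            p = ConsecutiveParams(min_snp=2, max_het=2, max_missing=2,
                                  min_length_bp=0)
            segs = detect_consecutive(make_gm(calls, pos=pos), p)
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.end_bp < b.start_bp


class TestWindowSupport:
    def test_uniform_hom_full_support(self):
        sup = snp_window_support(np.full(40, H, dtype=np.uint8),
                                 SlidingParams(window_snp=20))
        np.testing.assert_allclose(sup, 1.0)

    def test_all_het_zero_support(self):
        sup = snp_window_support(np.full(40, E, dtype=np.uint8),
                                 SlidingParams(window_snp=20))
        np.testing.assert_allclose(sup, 0.0)

    def test_short_chromosome_zero_support(self):
        sup = snp_window_support(np.full(10, H, dtype=np.uint8),
                                 SlidingParams(window_snp=20))
        assert sup.shape == (10,) and (sup == 0).all()

    def test_single_het_support_profile(self):
        """One HET among 60 HOM with window 20: support 0 at the het (every
        covering window contains it), recovering with distance, matching
        exhaustive enumeration."""
        calls = np.full(60, H, dtype=np.uint8)
        calls[30] = E
        p = SlidingParams(window_snp=20, window_max_het=0)
        sup = snp_window_support(calls, p)
        assert sup[30] == 0.0
        assert sup[0] == 1.0 and sup[-1] == 1.0
        assert sup[25] < sup[15] <= 1.0  # support recovers with distance
        np.testing.assert_allclose(
            sup, brute_force_window_support(calls, 20, 0, 0))

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            _, calls = random_chromosome(rng)
            w = int(rng.integers(2, 12))
            mh = int(rng.integers(0, 3))
            mm = int(rng.integers(0, 3))
            p = SlidingParams(window_snp=w, window_max_het=mh, window_max_missing=mm)
            np.testing.assert_allclose(
                snp_window_support(calls, p),
                brute_force_window_support(calls, w, mh, mm))


class TestDetectSliding:
    def test_uniform_hom_single_segment(self):
        gm = make_gm([H] * 40, pos=(np.arange(40) + 1) * 50_000)  # 2 Mb span
        segs = detect_sliding(gm, SlidingParams(window_snp=20, min_snp=20))
        assert len(segs) == 1 and segs[0].n_snp == 40

    def test_too_few_snps_for_a_window(self):
        gm = make_gm([H] * 10)
        assert detect_sliding(gm, SlidingParams(window_snp=20, min_snp=5)) == []

    def test_density_filter(self):
        """40 HOM SNPs at 100 kb spacing fail a 60 kb/SNP density bound."""
        gm = make_gm([H] * 40)  # 100 kb spacing
        p60 = SlidingParams(window_snp=20, min_snp=20, max_bp_per_snp=60_000)
        assert detect_sliding(gm, p60) == []
        p1m = dataclasses.replace(p60, max_bp_per_snp=1_000_000)
        assert len(detect_sliding(gm, p1m)) == 1

    def test_het_call_not_inside_run_at_zero_budget(self):
        calls = [H] * 60
        calls[30] = E
        gm = make_gm(calls, pos=(np.arange(60) + 1) * 50_000)
        segs = detect_sliding(gm, SlidingParams(window_snp=10, min_snp=10))
        assert len(segs) == 2
        for s in segs:
            assert s.n_het == 0
            assert not (s.start_bp <= 31 * 50_000 <= s.end_bp)

    def test_gap_splits_candidates(self):
        pos = np.concatenate([
            (np.arange(30) + 1) * 50_000,
            1_500_000 + 2_000_000 + np.arange(30) * 50_000,
        ])
        gm = make_gm([H] * 60, pos=pos)
        segs = detect_sliding(gm, SlidingParams(window_snp=10, min_snp=10))
        assert len(segs) == 2


class TestPresets:
    def test_paper_style_presets(self):
        c20 = get_preset("consecutive-20")
        assert (c20.min_snp, c20.max_het, c20.max_missing) == (20, 0, 0)
        assert (c20.min_length_bp, c20.max_gap_bp) == (250_000, 1_000_000)
        plink = get_preset("plink-paper")
        assert (plink.window_snp, plink.window_threshold, plink.min_snp) == (20, 0.05, 20)
        assert plink.max_bp_per_snp == 60_000
        s20 = get_preset("sliding-20")
        assert s20.max_bp_per_snp == 1_000_000

    def test_override_and_unknown(self):
        assert get_preset("consecutive-20", max_het=2).max_het == 2
        with pytest.raises(KeyError):
            get_preset("nope")
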