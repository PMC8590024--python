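import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_gm
from estuarscan import popgen_stats as ps
from oracles import brute_hudson_fst, brute_pi, brute_tajima_d


class TestSlidingWindows:
    def test_enumeration(self):
        ws = ps.sliding_windows(120_000)
        assert [(w.start, w.end) for w in ws] == [
            (0, 100_000), (10_000, 110_000), (20_000, 120_000)]

    def test_exact_fit_gives_one_window(self):
        assert len(ps.sliding_windows(100_000)) == 1

    def test_too_short_full_only_is_empty(self):
        with pytest.warns(UserWarning):
            assert ps.sliding_windows(99_999) == []

    def test_truncation_mode(self):
        ws = ps.sliding_windows(115_000, full_only=False)
        assert (ws[0].start, ws[0].end) == (0, 100_000)
        assert (ws[1].start, ws[1].end) == (10_000, 110_000)  # still full
        assert (ws[2].start, ws[2].end) == (20_000, 115_000)  # truncated
        assert ws[-1].end == 115_000
        assert all(w.length <= 100_000 for w in ws)

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            ps.sliding_windows(10_000, size=10, step=20)


class TestWindowPi:
    def test_single_site_worked_example(self):
        # 2 diploids = 4 alleles, x = 2 -> per-site 2/3; L = 100
        gm = make_gm([[1, 1]], positions=[5])
        w = ps.Window("chr1", 0, 100)
        assert ps.window_pi(gm, w, "P1") == pytest.approx(2 / 3 / 100, abs=1e-12)

    def test_monomorphic_window_is_zero(self):
        gm = make_gm([[0, 0], [2, 2]], positions=[5, 6])
        assert ps.window_pi(gm, ps.Window("chr1", 0, 100), "P1") == 0.0

    def test_agrees_with_bruteforce(self, rng):
        from oracles import random_genotypes
        for _ in range(10):
            codes = random_genotypes(rng, 30, 5, missing_rate=0.1)
            gm = make_gm(codes)
            w = ps.Window("chr1", 0, 300)
            assert ps.window_pi(gm, w, "P1") == pytest.approx(
                brute_pi(codes, 300), abs=1e-12)


class TestThetaW:
    def test_worked_value(self):
        # S = 3 segregating sites, n = 4 alleles: theta = S/a1 = 3/1.8333...
        a1 = ps.tajima_constants(4)["a1"]
        assert 3 / a1 == pytest.approx(1.6364, abs=5e-4)
        gm = make_gm([[1, 0], [1, 1], [2, 1]], positions=[0, 1, 2])
        w = ps.Window("chr1", 0, 3)
        assert ps.window_theta_w(gm, w, "P1") == pytest.approx(3 / a1 / 3, rel=1e-12)

    def test_no_segregation_gives_zero(self):
        gm = make_gm([[0, 0]], positions=[0])
        assert ps.window_theta_w(gm, ps.Window("chr1", 0, 10), "P1") == 0.0

    def test_doubling_length_halves_theta(self):
        gm = make_gm([[1, 0], [1, 1]], positions=[0, 1])
        t1 = ps.window_theta_w(gm, ps.Window("chr1", 0, 10), "P1")
        t2 = ps.window_theta_w(gm, ps.Window("chr1", 0, 20), "P1")
        assert t1 == pytest.approx(2 * t2, rel=1e-12)


class TestTajimasD:
    def test_four_haplotype_worked_example(self):
        # haplotypes {000, 001, 011, 111}: S=3, pi_hat=5/3, D ~ 0.168
        H = np.array([[0, 0, 0, 1], [0, 0, 1, 1], [0, 1, 1, 1]])
        S, pi_hat, d = ps.haplotype_stats(H)
        assert (S, pi_hat) == (3, pytest.approx(5 / 3, rel=1e-12))
        assert d == pytest.approx(0.168, abs=1e-3)
        # same allele counts as diploid codes give the identical statistic
        gm = make_gm([[1, 0], [1, 1], [2, 1]], positions=[0, 1, 2])
        assert ps.tajimas_d(gm, ps.Window("chr1", 0, 10), "P1") == pytest.approx(d)

    def test_matches_independent_constants(self, rng):
        from oracles import random_genotypes
        for _ in range(10):
            codes = random_genotypes(rng, 40, 6)
            gm = make_gm(codes)
            got = ps.tajimas_d(gm, ps.Window("chr1", 0, 400), "P1")
            want = brute_tajima_d(codes)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_excess_singletons_is_negative(self):
        # every variant a singleton in a sample of 10 diploids
        codes = np.zeros((12, 10), dtype=np.int8)
        codes[np.arange(12), np.arange(12) % 10] = 1
        gm = make_gm(codes)
        assert ps.tajimas_d(gm, ps.Window("chr1", 0, 200), "P1") < 0

    def test_undefined_cases_flagged_not_raised(self):
        gm = make_gm([[0, 0]], positions=[0])
        assert math.isnan(ps.tajimas_d(gm, ps.Window("chr1", 0, 10), "P1"))


class TestHudsonFst:
    def test_single_site_worked_example(self):
        # p1=0.9, p2=0.1 with 10 alleles each: (0.64-0.01-0.01)/0.82
        codes = [[2, 2, 2, 2, 1] + [0, 0, 0, 0, 1]]
        gm = make_gm(codes, pops=["A"] * 5 + ["B"] * 5)
        fst, sn, sdn = ps.hudson_fst(gm, ps.Window("chr1", 0, 10), "A", "B")
        assert fst == pytest.approx(0.62 / 0.82, rel=1e-12)

    def test_equal_frequencies_near_zero(self):
        codes = [[1, 1, 0, 2, 1, 1, 0, 2]]
        gm = make_gm(codes, pops=["A"] * 4 + ["B"] * 4)
        fst, *_ = ps.hudson_fst(gm, ps.Window("chr1", 0, 10), "A", "B")
        assert fst <= 0 + 1e-12

    def test_fixed_difference_approaches_one(self):
        codes = [[2] * 20 + [0] * 20]
        gm = make_gm(codes, pops=["A"] * 20 + ["B"] * 20)
        fst, *_ = ps.hudson_fst(gm, ps.Window("chr1", 0, 10), "A", "B")
        assert fst == pytest.approx(1.0, abs=1e-12)

    def test_swap_invariance(self, rng):
        from oracles import random_genotypes
        codes = random_genotypes(rng, 25, 8)
        gm = make_gm(codes, pops=["A"] * 4 + ["B"] * 4)
        w = ps.Window("chr1", 0, 250)
        assert (ps.hudson_fst(gm, w, "A", "B")[0]
                == pytest.approx(ps.hudson_fst(gm, w, "B", "A")[0], abs=1e-12))

    def test_agrees_with_bruteforce(self, rng):
        from oracles import random_genotypes
        for _ in range(10):
            codes = random_genotypes(rng, 50, 10, missing_rate=0.05)
            gm = make_gm(codes, pops=["A"] * 5 + ["B"] * 5)
            got, *_ = ps.hudson_fst(gm, ps.Window("chr1", 0, 500), "A", "B")
            want = brute_hudson_fst(codes[:, :5], codes[:, 5:])
            assert got == pytest.approx(want, abs=1e-10)

    def test_site_fst_matches_single_site_windows(self, rng):
        from oracles import random_genotypes
        codes = random_genotypes(rng, 20, 8)
        gm = make_gm(codes, pops=["A"] * 4 + ["B"] * 4)
        per_site = ps.site_fst(gm, "A", "B")
        for i, pos in enumerate(gm.pos):
            w = ps.Window("chr1", int(pos), int(pos) + 1)
            fst, _, sdn = ps.hudson_fst(gm, w, "A", "B")
            if sdn > 0:
                assert per_site["fst"].iloc[i] == pytest.approx(fst, abs=1e-12)
            else:
                assert math.isnan(per_site["fst"].iloc[i])


class TestWindowedStats:
    def test_matches_per_window_functions(self, rng):
        from oracles import random_genotypes
        for missing in (0.0, 0.1):
            codes = random_genotypes(rng, 60, 10, missing_rate=missing)
            gm = make_gm(codes, positions=np.sort(
                rng.choice(5000, 60, replace=False)),
                pops=["A"] * 5 + ["B"] * 5)
            df = ps.windowed_stats(gm, {"chr1": 5000}, size=1000, step=500)
            for _, row in df.iterrows():
                w = ps.Window(row["chrom"], int(row["start"]), int(row["end"]))
                for p in ("A", "B"):
                    assert row[f"pi_{p}"] == pytest.approx(
                        ps.window_pi(gm, w, p), abs=1e-12)
                    d = ps.tajimas_d(gm, w, p)
                    if math.isnan(d):
                        assert math.isnan(row[f"D_{p}"])
                    else:
                        assert row[f"D_{p}"] == pytest.approx(d, abs=1e-10)
                fst, *_ = ps.hudson_fst(gm, w, "A", "B")
                if math.isnan(fst):
                    assert math.isnan(row["fst_A_B"])
                else:
                    assert row["fst_A_B"] == pytest.approx(fst, abs=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_invariants(self, seed):
        rng = np.random.default_rng(seed)
        from oracles import random_genotypes
        codes = random_genotypes(rng, 20, 6, missing_rate=0.1)
        gm = make_gm(codes)
        df = ps.windowed_stats(gm, {"chr1": 200}, size=100, step=50)
        assert (df["pi_P1"] >= 0).all()
        assert (df["theta_P1"].fillna(0) >= 0).all()
        # pi == 0 iff S == 0
        assert ((df["pi_P1"] == 0) == (df["S_P1"] == 0)).all()
        assert (df["fst_P1_P1"].dropna() <= 1.0).all() if "fst_P1_P1" in df else True


class TestLd:
    def test_identical_dosages(self):
        gm = make_gm([[0, 1, 2, 0], [0, 1, 2, 0]], positions=[0, 50])
        pairs = ps.ld_r2_pairs(gm, "chr1")
        assert pairs == [(50, pytest.approx(1.0))]

    def test_perfect_anticorrelation(self):
        gm = make_gm([[0, 1, 2, 0], [2, 1, 0, 2]], positions=[0, 50])
        assert ps.ld_r2_pairs(gm, "chr1")[0][1] == pytest.approx(1.0)

    def test_monomorphic_pair_skipped(self):
        gm = make_gm([[1, 1, 1, 1], [0, 1, 2, 0]], positions=[0, 50])
        assert ps.ld_r2_pairs(gm, "chr1") == []

    def test_max_dist_respected(self):
        gm = make_gm([[0, 1, 2, 0], [0, 1, 2, 0]], positions=[0, 5000])
        assert ps.ld_r2_pairs(gm, "chr1", max_dist=1000) == []

    def test_equilibrium_mean_r2_small(self, rng):
        # independent loci: E[r^2] ~ 1/n for n individuals
        n = 50
        codes = rng.binomial(2, 0.5, size=(40, n)).astype(np.int8)
        gm = make_gm(codes, positions=np.arange(40) * 10)
        pairs = ps.ld_r2_pairs(gm, "chr1")
        mean_r2 = np.mean([r for _, r in pairs])
        assert mean_r2 < 3.0 / n

    def test_half_decay_worked_example(self):
        curve = ps.LdDecayCurve(
            np.array([0, 1000, 2000, 3000]), np.array([1000, 2000, 3000, 4000]),
            np.array([0.4, 0.25, 0.20, 0.15]), np.array([10, 10, 10, 10]))
        assert ps.ld_half_decay(curve) == 2500.0

    def test_flat_curve_undefined(self):
        curve = ps.LdDecayCurve(
            np.array([0, 1000]), np.array([1000, 2000]),
            np.array([0.3, 0.3]), np.array([5, 5]))
        assert ps.ld_half_decay(curve) is None

    def test_empty_curve_raises(self):
        curve = ps.LdDecayCurve(np.array([0]), np.array([1000]),
                                np.array([np.nan]), np.array([0]))
        with pytest.raises(ValueError):
            ps.ld_half_decay(curve)

    def test_decay_curve_binning(self):
        pairs = [(50, 0.9), (150, 0.5), (160, 0.7), (999, 0.1)]
        curve = ps.ld_decay_curve(pairs, bin_width=100, max_dist=1000)
        assert curve.n_pairs[0] == 1 and curve.n_pairs[1] == 2
        assert curve.mean_r2[1] == pytest.approx(0.6)
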