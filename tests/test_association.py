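"""Distance-statistics tests: profiles, MDA, enrichment, both-ends, and the
model/results layer.  Every computation is checked against a deliberately
naive rotation/enumeration oracle on small circles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoqfp import (
    DeletionProximityModel,
    MotifBreakpointAssociation,
    both_ends_enrichment,
    chance_proximity_probability,
    enrichment_curve,
    enrichment_pvalue,
    mda,
    mean_min_distance,
    min_distance_profile,
    paired_repeat_both_ends,
)
from mitoqfp.genome import circular_distance, rotate_positions
from mitoqfp.motifs import RepeatPair, RepeatUnit

from conftest import (
    brute_chance_probability,
    brute_mda,
    brute_mean_min_distance,
    brute_min_distance,
)


def _rand_points(rng, L, n, halves=True):
    pts = rng.integers(1, L + 1, n).astype(float)
    if halves:
        pts = pts + rng.choice([0.0, 0.5], n)
    return list(pts)


def make_pair(m5, m3):
    u5 = RepeatUnit(start=m5, unit_length=1, k=1, repeat_class="direct",
                    midpoint=m5, partner_starts=())
    u3 = RepeatUnit(start=m3, unit_length=1, k=1, repeat_class="direct",
                    midpoint=m3, partner_starts=())
    return RepeatPair(unit5=u5, unit3=u3, word="")


class TestProfile:
    def test_single_midpoint(self):
        assert list(min_distance_profile([1.0], 10)) == [0, 1, 2, 3, 4, 5, 4, 3, 2, 1]

    def test_half_integer_midpoint(self):
        prof = min_distance_profile([2.5], 6)
        assert prof[1] == pytest.approx(0.5)  # position 2

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            min_distance_profile([], 10)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            L = int(rng.integers(5, 102))
            mids = _rand_points(rng, L, int(rng.integers(1, 6)))
            prof = min_distance_profile(mids, L)
            exp = [brute_min_distance(x, mids, L) for x in range(1, L + 1)]
            assert np.allclose(prof, exp)


class TestMeanMinDistance:
    def test_identical_sets_zero(self):
        assert mean_min_distance([3.0, 7.0], [3.0, 7.0], 20) == 0.0

    def test_asymmetry(self):
        assert mean_min_distance([1.0, 11.0], [1.0], 20) == 5.0
        assert mean_min_distance([1.0], [1.0, 11.0], 20) == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            L = int(rng.integers(10, 201))
            a = _rand_points(rng, L, int(rng.integers(1, 8)))
            b = _rand_points(rng, L, int(rng.integers(1, 8)))
            assert mean_min_distance(a, b, L) == pytest.approx(
                brute_mean_min_distance(a, b, L))


class TestMda:
    def test_forced_zero_p(self):
        res = mda([5.0], [5.0], 50)
        assert res.actual_mean == 0.0
        assert res.p_value == 0.0
        assert res.n_rotations == 49
        assert res.p_display().startswith("<")

    def test_small_instance_matches_rotation_oracle(self):
        L = 20
        res = mda([4.0, 15.0], [3.0, 11.0], L)
        actual, controls, p = brute_mda([4.0, 15.0], [3.0, 11.0], L)
        assert res.actual_mean == pytest.approx(actual)
        assert np.allclose(res.control_means, controls)
        assert res.p_value == pytest.approx(p)

    def test_random_instances_match_rotation_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            L = int(rng.integers(15, 150))
            a = _rand_points(rng, L, int(rng.integers(1, 7)))
            b = _rand_points(rng, L, int(rng.integers(1, 7)))
            res = mda(a, b, L)
            actual, controls, p = brute_mda(a, b, L)
            assert res.actual_mean == pytest.approx(actual)
            assert np.allclose(res.control_means, controls)
            assert res.p_value == pytest.approx(p)

    @given(st.integers(0, 10**6))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_p_invariant_under_joint_rotation(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(20, 80))
        a = _rand_points(rng, L, int(rng.integers(1, 6)), halves=False)
        b = _rand_points(rng, L, int(rng.integers(1, 6)), halves=False)
        r = int(rng.integers(0, L))
        base = mda(a, b, L)
        rot = mda(rotate_positions(a, r, L), rotate_positions(b, r, L), L)
        assert rot.p_value == base.p_value
        assert rot.actual_mean == pytest.approx(base.actual_mean)


class TestChanceProbability:
    def test_saturates_at_half_circumference(self):
        assert chance_proximity_probability([7.0], 50, 100) == 1.0

    def test_single_midpoint_window(self):
        assert chance_proximity_probability([50.0], 2, 100) == pytest.approx(5 / 100)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            L = int(rng.integers(10, 101))
            to = _rand_points(rng, L, int(rng.integers(1, 5)))
            D = float(rng.integers(0, L // 2 + 2))
            assert chance_proximity_probability(to, D, L) == pytest.approx(
                brute_chance_probability(to, D, L))

    def test_equals_rotation_average_of_single_point_indicator(self):
        # the identity the rotational null relies on
        rng = np.random.default_rng(6)
        L, D = 60, 4.0
        to = _rand_points(rng, L, 3)
        x = 17.0
        hits = [
            brute_min_distance(x, rotate_positions(to, r, L), L) <= D + 1e-12
            for r in range(L)
        ]
        assert chance_proximity_probability(to, D, L) == pytest.approx(np.mean(hits))


class TestBinomialPvalue:
    def test_boundary_exposes_convention_difference(self):
        assert enrichment_pvalue(10, 10, 1.0, "greater_than_K") == 0.0
        assert enrichment_pvalue(10, 10, 1.0, "at_least_K") == 1.0
        assert enrichment_pvalue(0, 10, 0.3, "at_least_K") == 1.0

    def test_direct_summation_oracle(self):
        from math import comb

        rng = np.random.default_rng(7)
        for _ in range(300):
            N = int(rng.integers(1, 40))
            K = int(rng.integers(0, N + 1))
            P = float(rng.random())
            ge = sum(comb(N, j) * P**j * (1 - P) ** (N - j) for j in range(K, N + 1))
            gt = sum(comb(N, j) * P**j * (1 - P) ** (N - j) for j in range(K + 1, N + 1))
            assert enrichment_pvalue(K, N, P, "at_least_K") == pytest.approx(ge, abs=1e-12)
            assert enrichment_pvalue(K, N, P, "greater_than_K") == pytest.approx(gt, abs=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            enrichment_pvalue(5, 3, 0.5)
        with pytest.raises(ValueError):
            enrichment_pvalue(1, 3, 1.5)


class TestEnrichmentCurve:
    def test_coincident_sets_saturate_at_zero(self):
        curve = enrichment_curve([5.0, 9.0], [5.0, 9.0], 40, d_max=5)
        assert curve.points[0].K == 2

    def test_k_reaches_n_at_half_circumference(self):
        rng = np.random.default_rng(8)
        L = 60
        a = _rand_points(rng, L, 6, halves=False)
        curve = enrichment_curve(a, _rand_points(rng, L, 3), L, d_max=L // 2)
        assert curve.points[-1].K == len(a)
        assert curve.points[-1].P == 1.0
        ks = [p.K for p in curve.points]
        ps = [p.P for p in curve.points]
        assert all(b >= a for a, b in zip(ks, ks[1:]))
        assert all(b >= a for a, b in zip(ps, ps[1:]))

    def test_toy_instance_matches_brute_force_at_every_d(self):
        rng = np.random.default_rng(9)
        L = 100
        a = _rand_points(rng, L, 8)
        b = _rand_points(rng, L, 4)
        curve = enrichment_curve(a, b, L, d_max=50)
        for pt in curve.points:
            K = sum(brute_min_distance(x, b, L) <= pt.D + 1e-12 for x in a)
            assert pt.K == K
            assert pt.P == pytest.approx(brute_chance_probability(b, pt.D, L))
            assert pt.expected == pytest.approx(len(a) * pt.P)

    def test_power_on_planted_association(self):
        # breakpoints placed within 5 nt of motifs: strong enrichment at D=10
        rng = np.random.default_rng(10)
        L = 16569
        mids = np.sort(rng.choice(L, 100, replace=False) + 1.0)
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            picks = mids[rng.integers(0, len(mids), 60)]
            bp = (np.rint(picks - 1 + rng.uniform(-5, 5, 60)) % L) + 1
            curve = enrichment_curve(list(bp), list(mids), L, d_max=10)
            hits += curve.points[-1].p_value <= 0.001
        assert hits >= 0.95 * n_runs


class TestBothEnds:
    def test_motifs_at_every_breakpoint(self):
        dels = np.array([[10, 40], [20, 55]])
        mids = [10.0, 40.0, 20.0, 55.0]
        res = both_ends_enrichment(dels, mids, 80, D=0.0)
        assert res.n_close == res.N == 2

    def test_toy_instance_matches_exhaustive_rotation_oracle(self):
        rng = np.random.default_rng(11)
        L, D = 60, 10.0
        dels = []
        for _ in range(4):
            a, b = rng.choice(L, 2, replace=False) + 1
            dels.append((min(a, b), max(a, b)))
        mids = _rand_points(rng, L, 3)
        res = both_ends_enrichment(np.array(dels), mids, L, D)

        def count(r):
            mm = rotate_positions(mids, r, L)
            return sum(
                brute_min_distance(b5, mm, L) <= D + 1e-9
                and brute_min_distance(b3, mm, L) <= D + 1e-9
                for (b5, b3) in dels
            )

        counts = [count(r) for r in range(L)]
        assert res.n_close == counts[0]
        assert res.P == pytest.approx(sum(counts[1:]) / ((L - 1) * len(dels)))
        assert res.p_value == pytest.approx(
            enrichment_pvalue(res.n_close, res.N, res.P, "at_least_K"))

    def test_paired_variant_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            L = int(rng.integers(40, 90))
            dels = []
            for _ in range(3):
                a, b = rng.choice(L, 2, replace=False) + 1
                dels.append((min(a, b), max(a, b)))
            pairs = [make_pair(float(rng.integers(1, L + 1)) + rng.choice([0.0, 0.5]),
                               float(rng.integers(1, L + 1)) + rng.choice([0.0, 0.5]))
                     for _ in range(int(rng.integers(1, 4)))]
            D = 3.0
            res = paired_repeat_both_ends(np.array(dels), pairs, L, D)

            def count(r):
                c = 0
                for b5, b3 in dels:
                    for p in pairs:
                        d5 = circular_distance(b5, ((p.unit5.midpoint - 1 + r) % L) + 1, L)
                        d3 = circular_distance(b3, ((p.unit3.midpoint - 1 + r) % L) + 1, L)
                        if d5 <= D + 1e-9 and d3 <= D + 1e-9:
                            c += 1
                            break
                return c

            counts = [count(r) for r in range(L)]
            assert res.n_close == counts[0]
            assert res.P == pytest.approx(sum(counts[1:]) / ((L - 1) * len(dels)))

    def test_paired_mode_distinguished_from_single_set(self):
        # deletion ends match unit5 of one pair and unit3 of ANOTHER pair:
        # close in single-motif-set mode, not in paired mode
        L = 60
        pairs = [make_pair(10.0, 30.0), make_pair(20.0, 40.0)]
        dels = np.array([[10, 40]])
        single = both_ends_enrichment(dels, [10.0, 30.0, 20.0, 40.0], L, D=0.0)
        paired = paired_repeat_both_ends(dels, pairs, L, D=0.0)
        assert single.n_close == 1
        assert paired.n_close == 0
        # matching one pair end-to-end qualifies in paired mode
        assert paired_repeat_both_ends(np.array([[10, 30]]), pairs, L, 0.0).n_close == 1


class TestModelLayer:
    def test_fit_summarizes_both_directions(self):
        rng = np.random.default_rng(13)
        L = 500
        mids = _rand_points(rng, L, 8)
        bps = _rand_points(rng, L, 20, halves=False)
        res = MotifBreakpointAssociation(mids, bps, L,
                                         motif_name="2G_QFP",
                                         breakpoint_name="5p").fit(d_max=20)
        row = res.summary_row()
        assert row["n_motifs"] == 8 and row["n_breakpoints"] == 20
        assert 0 <= row["bp_to_motif_p"] <= 1
        text = res.summary()
        assert "2G_QFP" in text and "b-p -> motif" in text
        assert res.mda_bp_to_motif.n_rotations == L - 1
        # direction objects agree with the primitive calls
        direct = mda(bps, mids, L)
        assert res.mda_bp_to_motif.p_value == direct.p_value

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            MotifBreakpointAssociation([], [1.0], 100)

    def test_proximity_model_dispatch(self):
        dels = np.array([[10, 30]])
        single = DeletionProximityModel(dels, [10.0, 30.0], 60, D=0).fit()
        assert single.mode == "single_motif_set" and single.n_close == 1
        paired = DeletionProximityModel(dels, [make_pair(10.0, 30.0)], 60, D=0).fit()
        assert paired.mode == "paired_repeats" and paired.n_close == 1
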