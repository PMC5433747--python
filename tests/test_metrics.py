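import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from seedshift import (
    climate_lag,
    diversity_partition,
    inverse_simpson,
    jaccard_mean,
    percent_change,
    weighted_geomean_sm,
)
from seedshift.engine import EventLog
from seedshift.errors import UndefinedChangeError
from seedshift.metrics import count_events


class TestInverseSimpson:
    @pytest.mark.parametrize("n", [1, 3, 10])
    def test_equal_shares_give_effective_count(self, n):
        assert inverse_simpson(np.full(n, 2.5)) == pytest.approx(n)

    def test_two_species_unequal(self):
        assert inverse_simpson(np.array([0.7, 0.3])) == pytest.approx(1 / 0.58)

    def test_empty_community_sentinel(self):
        assert inverse_simpson(np.zeros(4)) == 0.0

    def test_scale_invariant(self, rng):
        a = rng.uniform(0, 5, 20)
        assert inverse_simpson(a) == pytest.approx(inverse_simpson(a * 37.2))


class TestDiversityPartition:
    def test_identical_patches_beta_one(self):
        B = np.tile(np.array([3.0, 1.0, 2.0]), (4, 1))
        alpha, beta, gamma = diversity_partition(B)
        assert beta == pytest.approx(1.0)
        assert gamma == pytest.approx(alpha)

    def test_monodominant_distinct_patches(self):
        B = np.eye(5) * 7.0
        alpha, beta, gamma = diversity_partition(B)
        assert alpha == pytest.approx(1.0)
        assert gamma == pytest.approx(5.0)
        assert beta == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self, rng):
        B = rng.uniform(0, 10, (4, 6))
        alpha, beta, gamma = diversity_partition(B)
        # brute force per definition
        alphas = []
        for row in B:
            p = row / row.sum()
            alphas.append(1.0 / np.sum(p**2))
        a_o = np.mean(alphas)
        reg = B.sum(axis=0)
        p = reg / reg.sum()
        g_o = 1.0 / np.sum(p**2)
        assert alpha == pytest.approx(a_o, abs=1e-12)
        assert gamma == pytest.approx(g_o, abs=1e-12)
        assert beta == pytest.approx(g_o / a_o, abs=1e-12)

    def test_empty_metacommunity_sentinel(self):
        assert diversity_partition(np.zeros((3, 4))) == (0.0, 0.0, 0.0)

    def test_species_permutation_invariant(self, rng):
        B = rng.uniform(0, 10, (5, 8))
        perm = rng.permutation(8)
        assert np.allclose(diversity_partition(B), diversity_partition(B[:, perm]))


class TestJaccard:
    def test_identical_communities(self):
        P = np.tile(np.array([True, False, True]), (3, 1))
        assert jaccard_mean(P) == 0.0

    def test_disjoint_communities(self):
        P = np.array([[True, False], [False, True]])
        assert jaccard_mean(P) == 1.0

    def test_partial_overlap(self):
        # {A,B} vs {B,C}: 1 - 1/3
        P = np.array([[True, True, False], [False, True, True]])
        assert jaccard_mean(P) == pytest.approx(2 / 3)

    def test_mutually_empty_pair_contributes_zero(self):
        P = np.array([[False, False], [False, False], [True, False]])
        # pairs: (0,1)=0, (0,2)=1, (1,2)=1 -> mean 2/3
        assert jaccard_mean(P) == pytest.approx(2 / 3)


class TestWeightedGeomeanSM:
    def test_equal_weights(self):
        assert weighted_geomean_sm(np.array([1.0, 1.0]), np.array([1.0, 4.0])) == pytest.approx(2.0)

    def test_single_survivor(self):
        assert weighted_geomean_sm(np.array([0.0, 5.0]), np.array([1.0, 4.0])) == pytest.approx(4.0)

    def test_unequal_weights(self):
        got = weighted_geomean_sm(np.array([0.8, 0.2]), np.array([1.0, 4.0]))
        assert got == pytest.approx(np.exp(0.2 * np.log(4.0)))
        assert got == pytest.approx(1.3195, abs=1e-4)


class TestClimateLag:
    def test_perfectly_tracking_species_has_zero_lag(self):
        B = np.array([[5.0], [0.0]])
        temps = np.array([10.0, 12.0])
        lags, mean_abs, _ = climate_lag(B, temps, np.array([10.0]), np.array([1.0]), np.array([True]), n_focal=1)
        assert lags[0] == pytest.approx(0.0)
        assert mean_abs == pytest.approx(0.0)

    def test_single_patch_one_degree_warmer(self):
        B = np.array([[5.0], [0.0]])
        temps = np.array([11.0, 12.0])
        lags, _, _ = climate_lag(B, temps, np.array([10.0]), np.array([1.0]), np.array([True]), n_focal=1)
        assert lags[0] == pytest.approx(1.0)

    def test_hand_worked_three_species(self):
        # sp0: all biomass in patch at 12 -> lag 12-10=+2
        # sp1: biomass 1:3 over patches at 10,12 -> mean T 11.5, lag 11.5-11=+0.5
        # sp2: all in patch at 10 -> lag 10-12=-2
        B = np.array([[0.0, 1.0, 4.0], [2.0, 3.0, 0.0]])
        temps = np.array([10.0, 12.0])
        t_opt = np.array([10.0, 11.0, 12.0])
        sm = np.array([1.0, 2.0, 3.0])
        natives = np.array([True, True, True])
        lags, mean_abs, corr = climate_lag(B, temps, t_opt, sm, natives, n_focal=3)
        assert np.allclose(lags, [2.0, 0.5, -2.0], atol=1e-10)
        assert mean_abs == pytest.approx(4.5 / 3)
        abs_lag = np.abs(np.array([2.0, 0.5, -2.0]))
        oracle = np.corrcoef(abs_lag, sm)[0, 1]
        assert corr == pytest.approx(oracle, abs=1e-10)

    def test_focal_set_restricted_to_warmest_natives(self):
        B = np.ones((1, 4))
        temps = np.array([10.0])
        t_opt = np.array([8.0, 9.0, 10.0, 11.0])
        sm = np.ones(4)
        natives = np.array([True, True, True, False])
        lags, _, _ = climate_lag(B, temps, t_opt, sm, natives, n_focal=2)
        # warmest two natives are T_opt 9 and 10
        assert np.allclose(sorted(lags), [0.0, 1.0])


class TestEvents:
    def test_no_changes_zero_counts(self):
        log = EventLog(years=[1, 2], colonisations=[np.zeros(5)] * 2, exclusions=[np.zeros(5)] * 2)
        assert count_events(log, 1, 2, 5) == (0.0, 0.0)

    def test_single_event_averaged_over_patches(self):
        col = np.zeros(50)
        col[3] = 1.0
        log = EventLog(years=[1], colonisations=[col], exclusions=[np.zeros(50)])
        c, e = count_events(log, 1, 10, 50)
        assert c == pytest.approx(0.02)
        assert e == 0.0

    def test_matches_brute_force_recount(self, rng):
        # random presence series -> events per definitions, cross-checked
        years = list(range(1, 6))
        P, S = 4, 7
        presence = rng.random((len(years) + 1, P, S)) > 0.5
        log = EventLog()
        for i, y in enumerate(years):
            gained = presence[i + 1] & ~presence[i]
            lost = presence[i] & ~presence[i + 1]
            log.years.append(y)
            log.colonisations.append(gained.sum(axis=1).astype(float))
            log.exclusions.append(lost.sum(axis=1).astype(float))
        c, e = count_events(log, 2, 4, P)
        gained_total = sum(
            (presence[i + 1] & ~presence[i]).sum() for i, y in enumerate(years) if 2 <= y <= 4
        )
        lost_total = sum(
            (presence[i] & ~presence[i + 1]).sum() for i, y in enumerate(years) if 2 <= y <= 4
        )
        assert c == pytest.approx(gained_total / P)
        assert e == pytest.approx(lost_total / P)


class TestMetricInvariants:
    @settings(derandomize=True, max_examples=50)
    @given(arrays(float, st.integers(1, 30), elements=st.floats(0.01, 1e6)))
    def test_inverse_simpson_between_one_and_richness(self, a):
        d = inverse_simpson(a)
        assert 1.0 - 1e-9 <= d <= a.size + 1e-9

    @settings(derandomize=True, max_examples=50)
    @given(
        arrays(float, (4, 6), elements=st.floats(0.0, 100.0)),
        st.randoms(use_true_random=False),
    )
    def test_partition_permutation_invariant_and_consistent(self, B, rand):
        if B.sum() == 0:
            return
        perm = list(range(B.shape[1]))
        rand.shuffle(perm)
        a1, b1, g1 = diversity_partition(B)
        a2, b2, g2 = diversity_partition(B[:, perm])
        assert a1 == pytest.approx(a2) and g1 == pytest.approx(g2)
        if a1 > 0:
            assert b1 == pytest.approx(g1 / a1)

    @settings(derandomize=True, max_examples=50)
    @given(arrays(bool, (5, 8)))
    def test_jaccard_bounded(self, P):
        assert 0.0 <= jaccard_mean(P) <= 1.0


class TestPercentChange:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(120.0, 120.0, 0.0), (100.0, 61.0, -39.0), (70.9, 57.4, -19.04)],
    )
    def test_values(self, before, after, expected):
        assert percent_change(before, after) == pytest.approx(expected, abs=0.005)

    def test_zero_baseline_rejected(self):
        with pytest.raises(UndefinedChangeError):
            percent_change(0.0, 5.0)
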