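import itertools
import math

import numpy as np
import pytest
from scipy.special import logit

from occugof import (
    CovariateSet,
    DetectionArray,
    FitResult,
    ModelSpec,
    NeighborScheme,
    ParamVector,
    SimConfig,
    bootstrap_gof,
    count_joins,
    jc_expected,
    jc_statistic,
    mb_expected,
    mb_statistic,
    parametric_bootstrap,
    partition_cohorts,
    permutation_join_test,
    simulate_dataset,
    unit_history_prob,
)
from occugof._fastfit import batch_fit_intercept
from occugof.gof import _chisq
from occugof.models import fit

ALL_T = NeighborScheme.ALL_TEMPORAL
CONSEC = NeighborScheme.CONSECUTIVE


def _fake_fit(family, psi, *detection):
    """A converged FitResult at chosen probabilities (no data involved)."""
    beta = [50.0 if psi >= 1 else logit(psi)]
    if family == "basic":
        alpha = [logit(detection[0])]
    else:
        p0, p1 = detection
        alpha = [logit(p0), logit(p1) - logit(p0)]
    spec = ModelSpec(family=family)
    est = ParamVector(beta, alpha)
    return FitResult(spec, est, np.eye(len(beta) + len(alpha)), 0.0, True)


class TestCountJoins:
    def test_consecutive_counts_adjacent_pairs(self):
        assert count_joins(np.array([[1, 1, 0, 1.0]]), CONSEC) == 1

    def test_all_temporal_counts_all_pairs(self):
        assert count_joins(np.array([[1, 1, 0, 1.0]]), ALL_T) == 3

    def test_no_cross_station_joins(self):
        h = np.zeros((2, 3))
        h[0, 0] = 1
        h[1, 1] = 1
        assert count_joins(h, ALL_T) == 0
        assert count_joins(h, CONSEC) == 0

    def test_missing_cell_breaks_adjacency(self):
        assert count_joins(np.array([[1, np.nan, 1.0]]), CONSEC) == 0
        assert count_joins(np.array([[1, np.nan, 1.0]]), ALL_T) == 1

    def test_consecutive_never_exceeds_all_temporal(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            h = rng.choice([0.0, 1.0, np.nan], size=(3, 5), p=[0.4, 0.4, 0.2])
            assert count_joins(h, CONSEC) <= count_joins(h, ALL_T)


class TestChiSquare:
    def test_arithmetic(self):
        stat, flagged = _chisq(np.array([3.0, 1.0]), np.array([2.0, 2.0]))
        assert stat == pytest.approx(1.0)
        assert not flagged

    def test_perfect_fit_is_zero(self):
        stat, _ = _chisq(np.array([2.0, 3.0]), np.array([2.0, 3.0]))
        assert stat == 0.0

    def test_zero_expected_with_observation_is_sentinel(self):
        stat, flagged = _chisq(np.array([1.0]), np.array([0.0]))
        assert math.isinf(stat) and flagged

    def test_zero_expected_without_observation_skipped(self):
        stat, flagged = _chisq(np.array([0.0, 2.0]), np.array([0.0, 2.0]))
        assert stat == 0.0 and not flagged


class TestMBExpected:
    def test_uniform_history_law(self):
        # psi = 1, p = 0.5, one station, two nights: all four histories
        # equally likely, so a cohort of 4 expects one unit per history
        vals = np.array([[[0, 0]], [[0, 1]], [[1, 0]], [[1, 1.0]]])
        d = DetectionArray(vals)
        covs = CovariateSet.intercept_only(d)
        fr = _fake_fit("basic", 1.0, 0.5)
        hd = mb_expected(fr, d, covs, np.arange(4))
        np.testing.assert_allclose(hd.e_counts, np.ones(4))
        np.testing.assert_array_equal(hd.o_counts, np.ones(4))

    def test_zero_inflation_arithmetic(self):
        # psi = p = 0.5, single revisit: E_0 = N(0.25 + 0.5), E_1 = 0.25 N
        vals = np.array([[[0.0]], [[0.0]], [[1.0]], [[0.0]]])
        d = DetectionArray(vals)
        covs = CovariateSet.intercept_only(d)
        fr = _fake_fit("basic", 0.5, 0.5)
        hd = mb_expected(fr, d, covs, np.arange(4))
        by_history = dict(zip((int(h[0, 0]) for h in hd.histories), hd.e_counts))
        assert by_history[0] == pytest.approx(3.0)
        assert by_history[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("family", ["basic", "markov"])
    def test_matches_direct_history_probabilities(self, family, unbalanced_data):
        covs = CovariateSet.intercept_only(unbalanced_data)
        fr = (
            _fake_fit("basic", 0.7, 0.45)
            if family == "basic"
            else _fake_fit("markov", 0.7, 0.3, 0.7)
        )
        for _, members in partition_cohorts(unbalanced_data):
            hd = mb_expected(fr, unbalanced_data, covs, members)
            for t in range(len(hd.o_counts)):
                direct = sum(
                    unit_history_prob(
                        fr.spec, fr.estimate, covs, i, hd.histories[t], conditional=False
                    )
                    for i in members
                )
                assert hd.e_counts[t] == pytest.approx(direct, abs=1e-10)

    def test_requires_converged_fit(self, toy_data, toy_covs):
        fr = _fake_fit("basic", 0.5, 0.5)
        fr.converged = False
        with pytest.raises(ValueError):
            mb_expected(fr, toy_data, toy_covs, np.arange(toy_data.n_units))


class TestJoinCountExpected:
    def test_two_night_levels(self):
        # psi = 1, p = 0.5: only history 11 has a join, so E = (0.75N, 0.25N)
        vals = np.zeros((8, 1, 2))
        vals[0, 0, :] = 1
        d = DetectionArray(vals)
        covs = CovariateSet.intercept_only(d)
        jt = jc_expected(_fake_fit("basic", 1.0, 0.5), d, covs, np.arange(8), CONSEC)
        np.testing.assert_allclose(jt.e_counts, [6.0, 2.0])

    @pytest.mark.parametrize("family", ["basic", "markov"])
    @pytest.mark.parametrize("scheme", [ALL_T, CONSEC])
    def test_matches_bruteforce_enumeration(self, family, scheme, unbalanced_data):
        """Oracle: enumerate all 2^(observed cells) unit histories directly."""
        d = unbalanced_data
        covs = CovariateSet.intercept_only(d)
        fr = (
            _fake_fit("basic", 0.8, 0.35)
            if family == "basic"
            else _fake_fit("markov", 0.8, 0.2, 0.8)
        )
        for _, members in partition_cohorts(d):
            jt = jc_expected(fr, d, covs, members, scheme)
            mask = d.mask[members[0]]
            cells = [(a, b) for a in range(d.n_spatial) for b in range(d.n_temporal) if mask[a, b]]
            brute = np.zeros(len(jt.e_counts))
            for bits in itertools.product([0, 1], repeat=len(cells)):
                h = np.full(mask.shape, np.nan)
                for (a, b), v in zip(cells, bits):
                    h[a, b] = v
                prob = sum(
                    unit_history_prob(fr.spec, fr.estimate, covs, i, h, conditional=False)
                    for i in members
                )
                brute[count_joins(h, scheme)] += prob
            np.testing.assert_allclose(jt.e_counts, brute, atol=1e-10)
            assert jt.e_counts.sum() == pytest.approx(len(members), abs=1e-8)
            assert jt.o_counts.sum() == len(members)

    def test_all_temporal_matches_binomial_shortcut(self):
        """Under definition 1 with constant p, joins depend only on the
        per-station detection totals: BB = sum_j C(s_j, 2) with s_j
        binomial."""
        from math import comb

        from scipy.stats import binom

        j, k, psi, p = 2, 3, 0.75, 0.4
        d = DetectionArray(np.zeros((5, j, k)))
        covs = CovariateSet.intercept_only(d)
        jt = jc_expected(_fake_fit("basic", psi, p), d, covs, np.arange(5), ALL_T)
        # station-level distribution over C(s,2), convolved across stations
        station = np.zeros(comb(k, 2) + 1)
        for s in range(k + 1):
            station[comb(s, 2)] += binom.pmf(s, k, p)
        unit = np.convolve(station, station)
        expected = 5 * psi * unit
        expected[0] += 5 * (1 - psi)
        np.testing.assert_allclose(jt.e_counts, expected[: len(jt.e_counts)], atol=1e-10)

    def test_statistics_invariant_to_relabeling(self, sim_markov):
        covs = CovariateSet.intercept_only(sim_markov)
        fr = fit(ModelSpec("basic"), sim_markov, covs)
        mb0 = mb_statistic(sim_markov, covs, fr)
        jc0 = jc_statistic(sim_markov, covs, fr, CONSEC)
        perm = np.random.default_rng(1).permutation(sim_markov.n_units)
        shuffled = DetectionArray(sim_markov.values[perm])
        assert mb_statistic(shuffled, covs, fr) == pytest.approx(mb0)
        assert jc_statistic(shuffled, covs, fr, CONSEC) == pytest.approx(jc0)
        stations = DetectionArray(sim_markov.values[:, ::-1, :])
        assert jc_statistic(stations, covs, fr, CONSEC) == pytest.approx(jc0)


class TestParametricBootstrap:
    def test_result_accounting(self, sim_null):
        covs = CovariateSet.intercept_only(sim_null)
        fr = fit(ModelSpec("basic"), sim_null, covs)
        res = parametric_bootstrap("jc", sim_null, covs, fr, n_boot=40, seed=5, scheme=CONSEC)
        assert res.n_resamples_used + res.n_discarded == 40
        assert res.p_value == pytest.approx(
            (res.resample_stats >= res.statistic).mean()
        )
        assert 0.0 <= res.p_value <= 1.0

    def test_requires_converged_fit(self, sim_null):
        covs = CovariateSet.intercept_only(sim_null)
        fr = _fake_fit("basic", 0.8, 0.5)
        fr.converged = False
        with pytest.raises(ValueError):
            parametric_bootstrap("mb", sim_null, covs, fr, n_boot=5, seed=0)

    @pytest.mark.parametrize("family,p0,p1", [("basic", 0.5, 0.5), ("markov", 0.2, 0.8)])
    def test_batched_refits_match_general_fitter(self, family, p0, p1):
        """The sufficient-statistic Newton solver and the general-purpose
        optimizer agree on estimates and convergence flags."""
        vals, scalar = [], []
        for i in range(15):
            d = simulate_dataset(
                SimConfig(n_units=50, psi=0.8, p0=p0, p1=p1, seed=77), i
            )
            vals.append(d.values)
            scalar.append(fit(ModelSpec(family), d))
        theta, conv, _ = batch_fit_intercept(family, np.stack(vals))
        sc_theta = np.array([f.estimate.theta for f in scalar])
        sc_conv = np.array([f.converged for f in scalar])
        np.testing.assert_array_equal(conv, sc_conv)
        both = conv & sc_conv
        assert np.abs(theta[both] - sc_theta[both]).max() < 1e-3


class TestPermutationJoinTest:
    def test_constant_data_gives_p_one(self):
        d = DetectionArray(np.ones((4, 1, 3)))
        res = permutation_join_test(d, CONSEC, n_perm=49, seed=0)
        assert res.p_value == 1.0

    def test_single_detection_gives_p_one(self):
        v = np.zeros((4, 1, 3))
        v[0, 0, 1] = 1
        res = permutation_join_test(DetectionArray(v), CONSEC, n_perm=49, seed=0)
        assert res.statistic == 0
        assert res.p_value == 1.0

    def test_no_detections_rejected(self):
        with pytest.raises(ValueError):
            permutation_join_test(DetectionArray(np.zeros((3, 1, 2))), CONSEC)

    def test_matches_exhaustive_enumeration(self):
        """Oracle: enumerate every placement of the pooled detections over
        the naively occupied units' cells."""
        v = np.array([[[1, 1, 0.0]], [[0, 1, 0.0]]])
        d = DetectionArray(v)
        res = permutation_join_test(d, CONSEC, n_perm=4000, seed=8)
        cells = [(i, k) for i in range(2) for k in range(3)]
        totals = []
        for ones in itertools.combinations(range(6), 3):
            g = np.zeros((2, 1, 3))
            for c in ones:
                i, k = cells[c]
                g[i, 0, k] = 1
            totals.append(
                count_joins(g[0], CONSEC) + count_joins(g[1], CONSEC)
            )
        totals = np.array(totals)
        exact_p = (totals >= res.statistic).mean()
        assert res.p_value == pytest.approx(exact_p, abs=0.03)
        # full permutation distribution agrees level by level
        for level in np.unique(totals):
            exact = (totals == level).mean()
            emp = (res.resample_stats == level).mean()
            assert emp == pytest.approx(exact, abs=3 * np.sqrt(exact * (1 - exact) / 4000) + 1e-9)
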