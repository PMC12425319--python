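import numpy as np
import pytest

from conftest import build_panel
from drmap.core_data import DataError
from drmap.validation import (bayesian_rank_test, cv_metrics, dic,
                              holdout_split, rhat)
from test_posterior import _samples


class TestHoldoutSplit:
    def test_exact_count(self):
        panel = build_panel(np.ones((10, 10), int))
        train, held = holdout_split(panel, 0.1, seed=1)
        assert len(held.Y) == 10
        assert train.observed_mask.sum() == 90

    def test_deterministic_per_seed(self):
        panel = build_panel(np.ones((10, 10), int))
        _, h1 = holdout_split(panel, 0.1, seed=5)
        _, h2 = holdout_split(panel, 0.1, seed=5)
        _, h3 = holdout_split(panel, 0.1, seed=6)
        np.testing.assert_array_equal(h1.district_idx, h2.district_idx)
        assert not (np.array_equal(h1.district_idx, h3.district_idx)
                    and np.array_equal(h1.year_idx, h3.year_idx))

    def test_partition_of_observed_cells(self):
        rng = np.random.default_rng(2)
        mask = rng.random((8, 6)) < 0.8
        panel = build_panel(rng.poisson(5, (8, 6)) * mask, mask=mask)
        train, held = holdout_split(panel, 0.25, seed=3)
        held_set = set(zip(held.district_idx.tolist(), held.year_idx.tolist()))
        train_set = set(map(tuple, np.argwhere(train.observed_mask)))
        orig_set = set(map(tuple, np.argwhere(mask)))
        assert train_set | held_set == orig_set
        assert train_set & held_set == set()

    def test_fraction_bounds(self):
        panel = build_panel(np.ones((5, 5), int))
        with pytest.raises(DataError):
            holdout_split(panel, 1.0, seed=0)


class TestCvMetrics:
    def test_perfect_prediction_is_zero_error_full_coverage(self):
        rng = np.random.default_rng(4)
        Y = rng.poisson(8, 20).astype(float) + 1
        E = rng.uniform(2, 9, 20)
        smr = Y / E
        rep = cv_metrics(Y, E, smr, smr - 0.1, smr + 0.1,
                         years=np.repeat([2000, 2001], 10))
        for y, m in rep.per_year.items():
            assert m["median_relative_error"] == 0.0
            assert m["median_absolute_relative_error"] == 0.0
            assert m["median_error"] == 0.0
            assert m["median_absolute_error"] == 0.0
            assert m["coverage_pct"] == 100.0

    def test_single_cell_arithmetic(self):
        rep = cv_metrics(np.array([10.0]), np.array([10.0]),
                         np.array([1.2]), np.array([0.9]), np.array([1.5]),
                         years=[2005])
        m = rep.per_year[2005]
        assert m["median_error"] == pytest.approx(0.2)
        assert m["median_relative_error"] == pytest.approx(0.2)

    def test_medians_match_sort_oracle(self):
        rng = np.random.default_rng(6)
        Y = rng.poisson(6, 30).astype(float) + 1
        E = rng.uniform(3, 8, 30)
        pred = rng.uniform(0.5, 2.0, 30)
        years = np.repeat([2000, 2001, 2002], 10)
        rep = cv_metrics(Y, E, pred, pred - 1, pred + 1, years)
        smr = Y / E
        for y in (2000, 2001, 2002):
            sel = years == y
            err = np.sort(pred[sel] - smr[sel])
            med = (err[4] + err[5]) / 2
            assert rep.per_year[y]["median_error"] == pytest.approx(med,
                                                                    abs=1e-12)
            rel = np.sort((pred[sel] - smr[sel]) / smr[sel])
            assert rep.per_year[y]["median_relative_error"] == pytest.approx(
                (rel[4] + rel[5]) / 2, abs=1e-12)

    def test_zero_counts_excluded_from_relative_only(self):
        Y = np.array([0.0, 5.0, 5.0])
        E = np.array([5.0, 5.0, 5.0])
        pred = np.array([0.4, 1.0, 1.0])
        rep = cv_metrics(Y, E, pred, pred - 1, pred + 1, years=[2000] * 3)
        assert rep.n_excluded_relative == 1
        assert rep.per_year[2000]["median_relative_error"] == 0.0
        # zero-count cell still enters the absolute metrics
        assert rep.per_year[2000]["median_absolute_error"] == pytest.approx(0.0)
        assert rep.per_year[2000]["n_cells"] == 3

    def test_absolute_metric_dominates_signed(self):
        rng = np.random.default_rng(8)
        Y = rng.poisson(7, 25).astype(float) + 1
        E = rng.uniform(2, 10, 25)
        pred = rng.uniform(0.3, 2.5, 25)
        rep = cv_metrics(Y, E, pred, pred - 1, pred + 1, years=[2000] * 25)
        m = rep.per_year[2000]
        assert m["median_absolute_error"] >= abs(m["median_error"]) - 1e-12
        assert (m["median_absolute_relative_error"]
                >= abs(m["median_relative_error"]) - 1e-12)


class TestBayesianRankTest:
    def test_exact_predictions_contain_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.tile(obs, (50, 1))
        interval, includes = bayesian_rank_test(obs, pred)
        assert interval == (0.0, 0.0) and includes

    def test_uniform_shift_excludes_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.tile(obs + 10, (50, 1))
        interval, includes = bayesian_rank_test(obs, pred)
        assert interval[0] > 0 and not includes

    def test_statistic_matches_enumeration_oracle(self):
        obs = np.array([1.0, 2.0])
        pred = np.array([[1.5, 1.0], [0.5, 3.0]])
        # draw 0: diffs (0.5, -1.0), signed ranks (+1, -2) -> mean -0.5
        # draw 1: diffs (-0.5, 1.0), signed ranks (-1, +2) -> mean +0.5
        interval, includes = bayesian_rank_test(obs, pred, interval=100.0)
        assert interval[0] == pytest.approx(-0.5)
        assert interval[1] == pytest.approx(0.5)
        assert includes


class TestRhat:
    def test_identical_chains_give_unity(self):
        c = np.sin(np.arange(100.0))
        assert rhat([c, c]) == pytest.approx(1.0, abs=0.05)

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)
        r = rhat([a, b])
        assert r > 1.5
        # formula oracle over the four half-chains
        halves = [a[:500], a[500:], b[:500], b[500:]]
        W = np.mean([np.var(h, ddof=1) for h in halves])
        B = 500 * np.var([h.mean() for h in halves], ddof=1)
        assert r == pytest.approx(np.sqrt((W * 499 / 500 + B / 500) / W))

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(10)
        chains = rng.normal(0, 1, size=(2, 400))
        ours = rhat(chains)
        theirs = float(az.rhat(chains[None].transpose(1, 2, 0)[..., 0],
                               method="split"))
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_split_detects_within_chain_trend(self):
        rng = np.random.default_rng(11)
        drift = np.linspace(0, 3, 1000)
        chains = [drift + rng.normal(0, 0.1, 1000) for _ in range(2)]
        assert rhat(chains) > 1.5   # halves disagree even though chains agree

    def test_stationary_chains_below_threshold(self):
        rng = np.random.default_rng(12)
        chains = rng.normal(size=(2, 2000))
        assert rhat(chains) < 1.05

    def test_zero_variance_reports_unity(self):
        assert rhat([np.ones(10), np.ones(10)]) == 1.0


class TestDic:
    def test_point_mass_posterior_has_zero_pd(self):
        lam = np.full((5, 2, 2), 1.3)
        panel = build_panel(np.full((2, 2), 3), E=np.full((2, 2), 2.0))
        rep = dic(_samples(np.log(lam)), panel)
        assert rep.p_d == pytest.approx(0.0, abs=1e-9)
        assert rep.dic == pytest.approx(rep.dbar)

    def test_two_draw_arithmetic_oracle(self):
        from scipy.stats import poisson
        lam = np.array([[[1.0]], [[2.0]]])
        panel = build_panel([[3]], E=[[2.0]])
        rep = dic(_samples(np.log(lam)), panel)
        d1 = -2 * poisson.logpmf(3, 2.0)
        d2 = -2 * poisson.logpmf(3, 4.0)
        dbar = (d1 + d2) / 2
        # posterior mean of log-lambda, not of lambda
        mu_bar = 2.0 * np.exp((np.log(1.0) + np.log(2.0)) / 2)
        dhat = -2 * poisson.logpmf(3, mu_bar)
        assert rep.dbar == pytest.approx(dbar)
        assert rep.p_d == pytest.approx(dbar - dhat)
        assert rep.dic == pytest.approx(2 * dbar - dhat)

    def test_masked_cell_leaves_dic_unchanged(self):
        lam = np.exp(np.random.default_rng(13).normal(0, 0.1, (10, 2, 2)))
        base = build_panel([[3, 4], [5, 6]], E=np.full((2, 2), 2.0),
                           mask=[[True, False], [True, True]])
        other = build_panel([[3, 999], [5, 6]], E=np.full((2, 2), 2.0),
                            mask=[[True, False], [True, True]])
        assert dic(_samples(np.log(lam)), base).dic == pytest.approx(
            dic(_samples(np.log(lam)), other).dic)
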