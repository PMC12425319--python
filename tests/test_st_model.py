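import numpy as np
import pytest
from scipy import stats

from conftest import build_panel
from drmap.core_data import DataError, RunConfig, make_district_graph
from drmap.st_model import (ModelState, fit, icar_conditional, load_samples,
                            log_likelihood, save_samples)


def _state(n, T, **kw):
    defaults = dict(alpha=0.0, beta=np.zeros(0), U=np.zeros(n), V=np.zeros(n),
                    X_t=np.zeros(T), eps=np.zeros((n, T)))
    defaults.update(kw)
    return ModelState(**defaults)


def _line_graph(n):
    ids = [f"d{i:02d}" for i in range(n)]
    return make_district_graph(ids, [(ids[i], ids[i + 1])
                                     for i in range(n - 1)])


class TestLogLikelihood:
    def test_poisson_zero_count_unit_mean(self):
        panel = build_panel([[0]], E=[[1.0]])
        assert log_likelihood(_state(1, 1), panel) == pytest.approx(-1.0)

    def test_matches_poisson_pmf_oracle(self):
        panel = build_panel([[2]], E=[[1.0]])
        state = _state(1, 1, alpha=np.log(2.0))   # lambda = 2
        assert log_likelihood(state, panel) == pytest.approx(
            stats.poisson.logpmf(2, 2.0))

    def test_random_panel_matches_pmf_sum(self, small_panel):
        rng = np.random.default_rng(0)
        n, T = small_panel.Y.shape
        state = _state(n, T, alpha=0.3, eps=rng.normal(0, 0.2, (n, T)))
        mu = small_panel.E * np.exp(0.3 + state.eps)
        oracle = stats.poisson.logpmf(small_panel.Y, mu).sum()
        assert log_likelihood(state, small_panel) == pytest.approx(oracle)

    def test_masked_cell_contributes_zero(self):
        full = build_panel([[3, 4]], E=[[2.0, 2.0]])
        masked = build_panel([[3, 99]], E=[[2.0, 2.0]],
                             mask=[[True, False]])
        only_first = build_panel([[3]], E=[[2.0]])
        s2, s1 = _state(1, 2), _state(1, 1)
        assert log_likelihood(s2, masked) == pytest.approx(
            log_likelihood(s1, only_first))
        assert log_likelihood(s2, masked) != log_likelihood(s2, full)

    def test_nonfinite_predictor_names_cell(self):
        panel = build_panel([[1]], E=[[1.0]])
        state = _state(1, 1, alpha=np.inf)
        with pytest.raises(DataError, match="d00"):
            log_likelihood(state, panel)


class TestIcarConditional:
    def test_symmetric_neighbours(self):
        g = _line_graph(3)
        U = np.array([1.0, 0.0, -1.0])
        mean, prec = icar_conditional(U, g, tau_u=3.0, district="d01")
        assert mean == pytest.approx(0.0)
        assert prec == pytest.approx(6.0)

    def test_single_neighbour(self):
        g = _line_graph(2)
        mean, prec = icar_conditional(np.array([0.5, 2.0]), g, 4.0, "d01")
        assert (mean, prec) == (pytest.approx(0.5), pytest.approx(4.0))

    def test_four_cycle_matches_neighbour_average(self, square_graph):
        rng = np.random.default_rng(1)
        U = rng.normal(size=4)
        nbrs = {"A": ["B", "C"], "B": ["A", "D"],
                "C": ["A", "D"], "D": ["B", "C"]}
        idx = square_graph.index
        for d, nb in nbrs.items():
            mean, prec = icar_conditional(U, square_graph, 2.5, d)
            assert mean == pytest.approx(np.mean([U[idx[x]] for x in nb]))
            assert prec == pytest.approx(2.5 * 2)

    def test_isolated_district_rejected(self):
        g = make_district_graph(["A", "B"], [])
        with pytest.raises(DataError, match="isolated"):
            icar_conditional(np.zeros(2), g, 1.0, "A")


def _toy_fit_inputs(seed=0, n=6, T=4):
    rng = np.random.default_rng(seed)
    g = _line_graph(n)
    E = rng.uniform(5, 30, (n, T))
    Y = rng.poisson(E * 0.8)
    covs = {"yos": rng.normal(2, 1, (n, T))}
    panel = build_panel(Y, E=E, covariates=covs)
    return panel, g


class TestFit:
    def test_retained_draw_count_contract(self):
        panel, g = _toy_fit_inputs()
        cfg = RunConfig(n_chains=2, iterations_per_chain=50, burn_in=49,
                        covariate_selection=("yos",), seed=1)
        s = fit(panel, g, cfg)
        assert s.n_draws == 2
        assert sorted(np.unique(s.chain_id)) == [0, 1]

    def test_sum_to_zero_every_draw(self):
        panel, g = _toy_fit_inputs()
        cfg = RunConfig(n_chains=1, iterations_per_chain=300, burn_in=100,
                        covariate_selection=("yos",), seed=2)
        s = fit(panel, g, cfg)
        assert np.max(np.abs(s.U.sum(axis=1))) < 1e-10

    def test_chain_seed_swap_permutes_pooled_draws(self):
        panel, g = _toy_fit_inputs()
        cfg = RunConfig(n_chains=2, iterations_per_chain=200, burn_in=100,
                        covariate_selection=("yos",), seed=3)
        s_ab = fit(panel, g, cfg, chain_seeds=[11, 22])
        s_ba = fit(panel, g, cfg, chain_seeds=[22, 11])
        np.testing.assert_array_equal(np.sort(s_ab.alpha), np.sort(s_ba.alpha))
        assert not np.array_equal(s_ab.alpha, s_ba.alpha)

    def test_masked_cell_value_is_bitwise_irrelevant(self):
        panel, g = _toy_fit_inputs()
        mask = panel.observed_mask.copy()
        mask[2, 1] = False
        a = panel.with_mask(mask)
        Yb = a.Y.copy()
        Yb[2, 1] = 999   # never read: mask is false there
        b = type(a)(district_ids=a.district_ids, years=a.years, Y=Yb,
                    E=a.E, covariates=a.covariates, observed_mask=mask)
        cfg = RunConfig(n_chains=1, iterations_per_chain=120, burn_in=60,
                        covariate_selection=("yos",), seed=4)
        sa, sb = fit(a, g, cfg), fit(b, g, cfg)
        np.testing.assert_array_equal(sa.log_lambda, sb.log_lambda)
        np.testing.assert_array_equal(sa.alpha, sb.alpha)

    def test_conjugate_gamma_poisson_limit(self):
        # Single cell, intercept only with a near-flat prior on log(mu):
        # posterior of E*lambda is Gamma(Y, 1).
        panel = build_panel([[7]], E=[[2.0]])
        g = make_district_graph(panel.district_ids, [])
        cfg = RunConfig(n_chains=2, iterations_per_chain=6000, burn_in=1000,
                        covariate_selection=(), components=(), seed=3)
        s = fit(panel, g, cfg)
        mu = 2.0 * np.exp(s.log_lambda[:, 0, 0])
        ks = stats.kstest(mu, stats.gamma(a=7).cdf).statistic
        assert ks < 0.05

    def test_misaligned_graph_rejected(self):
        panel, _ = _toy_fit_inputs()
        other = _line_graph(3)
        with pytest.raises(DataError, match="aligned"):
            fit(panel, other, RunConfig(iterations_per_chain=10, burn_in=5))

    def test_save_load_roundtrip(self, tmp_path):
        panel, g = _toy_fit_inputs()
        cfg = RunConfig(n_chains=2, iterations_per_chain=60, burn_in=30,
                        covariate_selection=("yos",), seed=5)
        s = fit(panel, g, cfg)
        save_samples(s, tmp_path / "samples.npz")
        r = load_samples(tmp_path / "samples.npz")
        np.testing.assert_array_equal(r.log_lambda, s.log_lambda)
        assert r.beta_names == s.beta_names
        assert r.covariate_transform == s.covariate_transform
        assert r.config.config_hash() == cfg.config_hash()
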