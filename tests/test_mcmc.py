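"""Sampler initialisation, conjugate algebra, diagnostics and engine behaviour."""

import numpy as np
import pytest
from scipy import stats

from nide.families import NIFamilySpec
from nide.mcmc import (MCMCConfig, cn_contamination_probability, gelman_rubin,
                       init_state, laplace_shape_conditional,
                       mixing_conditional, run_chains, slash_shape_conditional,
                       tau_eps_conditional)
from nide.simulate import SimulationConfig, generate_dataset
from nide.decisions import de_probability


class TestConjugateAlgebra:
    def test_precision_conditional_example(self):
        # two observations (1, -1), unit scales, mean 0 -> Gamma(2, 1.005)
        shape, rate = tau_eps_conditional([1.0, -1.0], [0.0, 0.0], [1.0, 1.0])
        assert shape == pytest.approx(2.0)
        assert rate == pytest.approx(1.005)

    def test_precision_conditional_linear_in_u(self):
        y, m = np.array([1.0, -2.0, 0.5]), np.zeros(3)
        u = np.array([0.5, 1.5, 2.0])
        _, r1 = tau_eps_conditional(y, m, u)
        _, r2 = tau_eps_conditional(y, m, 2 * u)
        assert r2 - 0.005 == pytest.approx(2 * (r1 - 0.005))

    def test_mixing_conditional_counts(self):
        # 10 genes, 4 DE -> p_DE ~ Beta(5, 7) i.e. Dirichlet(7, 5)
        np.testing.assert_allclose(mixing_conditional([6, 4]), [7.0, 5.0])
        np.testing.assert_allclose(mixing_conditional([3, 1, 0, 1, 0]),
                                   [4, 2, 1, 2, 1])

    def test_cn_contamination_weight(self):
        # lam=0.1, gam=0.25, zero residual: 0.1*0.5 / (0.1*0.5 + 0.9) = 1/19
        assert cn_contamination_probability(0.0, 1.0, 0.1, 0.25) == \
            pytest.approx(1.0 / 19.0)

    def test_shape_conditionals(self):
        shape, rate = slash_shape_conditional(np.ones(5))
        assert (shape, rate) == (6.0, pytest.approx(0.005))
        shape, rate = laplace_shape_conditional(np.array([1.0, 1.0]))
        assert (shape, rate) == (3.0, pytest.approx(2.005))


class TestGelmanRubin:
    def test_hand_evaluated_example(self):
        # W = 5/3, B = 20000 -> sqrt((0.75*5/3 + 5000)/(5/3)) = 54.779
        r = gelman_rubin([[1, 2, 3, 4], [101, 102, 103, 104]])
        assert r == pytest.approx(54.779, abs=0.01)

    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(0)
        r = gelman_rubin(rng.normal(size=(2, 5000)))
        assert 0.99 < r < 1.05

    def test_constant_chain_undefined(self):
        with pytest.raises(ValueError, match="within-chain variance"):
            gelman_rubin([[1.0, 1.0], [1.0, 1.0]])

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([[1.0, 2.0, 3.0]])


@pytest.fixture(scope="module")
def small_data():
    cfg = SimulationConfig(n_genes=40, n_reps=1, seed=99, delta=2.0,
                           group_sizes=(6, 5),
                           error_family=NIFamilySpec.normal())
    return generate_dataset(cfg, 1)


class TestInitState:
    def test_initial_values(self, small_data):
        data, _ = small_data
        cfg = MCMCConfig(n_iter=10, n_burnin=5, family=NIFamilySpec.normal())
        st = init_state(data, cfg, chain=0)
        assert (st.u == 1.0).all()
        assert (st.z == 0).all()
        assert np.allclose(st.p, 0.5)
        assert (st.nu == 0).all()  # normal family carries no shape
        assert (st.tau_eps > 0).all()

    def test_chains_differ_only_by_jitter(self, small_data):
        data, _ = small_data
        cfg = MCMCConfig(n_iter=10, n_burnin=5, family=NIFamilySpec.t(5.0))
        s0, s1 = init_state(data, cfg, 0), init_state(data, cfg, 1)
        assert not np.allclose(s0.mu, s1.mu)
        np.testing.assert_array_equal(s0.tau_eps, s1.tau_eps)
        np.testing.assert_array_equal(s0.nu, s1.nu)

    def test_zero_variance_gene_capped(self):
        from nide.model import ExpressionDataset
        vals = np.vstack([np.ones(6), np.arange(6.0)])
        data = ExpressionDataset(vals, ["a", "b"], ["A", "B"],
                                 np.array([0, 0, 0, 1, 1, 1]))
        st = init_state(data, MCMCConfig(n_iter=2, n_burnin=1), 0)
        assert np.isfinite(st.tau_eps).all() and st.tau_eps[0] <= 1e6


class TestRunChains:
    def test_deterministic_given_seed(self, small_data):
        data, _ = small_data
        cfg = MCMCConfig(n_iter=300, n_burnin=150, n_chains=2, seed=11,
                         family=NIFamilySpec.contaminated_normal(0.5, 0.5))
        a, b = run_chains(data, cfg), run_chains(data, cfg)
        np.testing.assert_array_equal(a.z, b.z)
        np.testing.assert_array_equal(a.p, b.p)
        np.testing.assert_array_equal(a.tau_eps, b.tau_eps)

    def test_keep_length_and_rhat_present(self, small_data):
        data, _ = small_data
        cfg = MCMCConfig(n_iter=400, n_burnin=200, n_chains=2, thin=2, seed=1)
        d = run_chains(data, cfg)
        assert d.n_keep == 100
        assert any(k.startswith("p[") for k in d.rhat)

    def test_posterior_ranking_tracks_t_statistic(self):
        # diffuse normal model should order genes like the two-sample |t|;
        # a continuum of shifts keeps the ranking informative at every rank
        from nide.model import ExpressionDataset
        # a ramp of shifts keeps pi spread smoothly over (0, 1) so the rank
        # comparison is informative at every position
        rng = np.random.default_rng(5)
        N, n1, n2 = 200, 12, 8
        shift = np.linspace(0.0, 3.0, N)
        vals = rng.normal(14.0, 1.0, size=(N, n1 + n2))
        vals[:, :n1] += shift[:, None]
        data = ExpressionDataset(vals, [f"g{i}" for i in range(N)],
                                 ["A", "B"],
                                 np.array([0] * n1 + [1] * n2))
        mc = MCMCConfig(n_iter=12000, n_burnin=2000, n_chains=2, seed=7,
                        family=NIFamilySpec.normal())
        pi = de_probability(run_chains(data, mc)).pi
        g1, g2 = data.group_values(0), data.group_values(1)
        tstat = np.abs(stats.ttest_ind(g1, g2, axis=1).statistic)
        rho = stats.spearmanr(pi, tstat).statistic
        assert rho > 0.9

    def test_pi_invariant_under_gene_reordering(self, small_data):
        from nide.model import ExpressionDataset
        data, _ = small_data
        cfg = MCMCConfig(n_iter=2500, n_burnin=1000, n_chains=1, seed=3,
                         family=NIFamilySpec.normal())
        pi = de_probability(run_chains(data, cfg)).pi
        perm = np.random.default_rng(0).permutation(data.n_genes)
        data_p = ExpressionDataset(data.values[perm],
                                   [data.gene_ids[i] for i in perm],
                                   data.group_names, data.group_of)
        pi_p = de_probability(run_chains(data_p, cfg)).pi
        # invariance is distributional; MC error bounds the discrepancy
        assert np.max(np.abs(pi_p - pi[perm])) < 0.12

    def test_scalar_table_shape(self, small_data):
        data, _ = small_data
        cfg = MCMCConfig(n_iter=100, n_burnin=50, n_chains=2, seed=2)
        tab = run_chains(data, cfg).scalar_table()
        assert len(tab) == 2 * 50
        assert {"chain", "iteration", "p0", "p1", "tau_mu0"} <= set(tab.columns)
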