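"""Unit and property tests for the variational graphical-regression core."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import graphreg as gr
from graphreg.model import _precompute, build_node_design, standardize

from conftest import exact_spike_slab_pips


# ---------------------------------------------------------------------------
# standardize
# ---------------------------------------------------------------------------


class TestStandardize:
    def test_simple_column(self):
        out, means, scales = standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0])
        assert means[0] == pytest.approx(2.0)
        assert scales[0] == pytest.approx(1.0)  # sample (n-1) sd convention

    def test_idempotent_on_standardized_column(self):
        col = np.array([[-1.0], [0.0], [1.0]])
        out, means, scales = standardize(col)
        np.testing.assert_allclose(out, col, atol=1e-12)
        assert means[0] == pytest.approx(0.0)

    def test_exempt_column_passes_through(self):
        arr = np.column_stack([np.ones(3), [1.0, 2.0, 3.0]])
        out, means, scales = standardize(arr, exempt=[True, False])
        np.testing.assert_allclose(out[:, 0], 1.0)
        assert (means[0], scales[0]) == (0.0, 1.0)

    def test_all_columns_unit_variance(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(50, 4)) * [1, 5, 0.2, 40] + [0, 3, -1, 10]
        out, _, _ = standardize(arr)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_zero_variance_column_raises(self):
        with pytest.raises(gr.DegenerateInputError, match="flat"):
            standardize(np.column_stack([np.full(4, 2.0), np.arange(4.0)]),
                        names=["flat", "ok"])


# ---------------------------------------------------------------------------
# build_node_design
# ---------------------------------------------------------------------------


class TestNodeDesign:
    def test_intercept_only_design_is_other_columns(self):
        y = np.arange(12.0).reshape(4, 3)
        x = np.ones((4, 1))
        d = build_node_design(y, x, 0, "undirected")
        np.testing.assert_allclose(d.design, y[:, 1:])
        assert d.index_map == [(1, 0), (2, 0)]

    def test_elementwise_product(self):
        y = np.array([[0.0, 2.0], [0.0, 5.0], [0.0, 1.0]])
        x = np.array([[1.0], [0.0], [1.0]])
        d = build_node_design(y, x, 0, "undirected")
        np.testing.assert_allclose(d.design[:, 0], [2.0, 0.0, 1.0])

    @pytest.mark.parametrize("p,q,mode,node,m", [
        (33, 2, "undirected", 0, 64),   # (p-1)*q
        (33, 2, "undirected", 32, 64),
        (5, 3, "dag", 0, 0),            # first node: valid empty design
        (5, 3, "dag", 4, 12),           # (i-1)*q
    ])
    def test_design_width(self, p, q, mode, node, m):
        rng = np.random.default_rng(1)
        d = build_node_design(rng.normal(size=(8, p)), rng.normal(size=(8, q)),
                              node, mode)
        assert d.m == m
        assert len(set(d.index_map)) == m  # bijective onto included pairs
        assert all(j != node for j, _ in d.index_map)

    def test_column_order_j_major(self):
        rng = np.random.default_rng(2)
        d = build_node_design(rng.normal(size=(5, 4)), rng.normal(size=(5, 2)),
                              2, "undirected")
        assert d.index_map == [(0, 0), (0, 1), (1, 0), (1, 1), (3, 0), (3, 1)]


# ---------------------------------------------------------------------------
# CAVI sweeps and the ELBO
# ---------------------------------------------------------------------------


def _toy_design(n=60, m=4, q=1, seed=0, beta=None, orthogonal=False):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, m))
    if orthogonal:
        Z, _ = np.linalg.qr(Z)
        Z *= np.sqrt(n)
    beta = np.zeros(m) if beta is None else np.asarray(beta, float)
    y = Z @ beta + rng.normal(size=n)
    index_map = [(j + 1, l) for j in range(m // q) for l in range(q)]
    return gr.NodeDesign(response=y, design=Z, index_map=index_map[:m], q=q, node=0)


class TestCaviSweep:
    def test_orthogonal_noise_column_shrinks(self, hyper):
        design = _toy_design(n=80, m=1, seed=3, orthogonal=True)
        design.response -= (design.design[:, 0] @ design.response
                            / (design.design[:, 0] @ design.design[:, 0])
                            ) * design.design[:, 0]  # exactly orthogonal
        from graphreg.model import _init_posterior
        post = _init_posterior(design, hyper)
        new = gr.cavi_sweep(design, post, hyper)
        assert new.alpha[0] < post.alpha[0]

    def test_sweep_is_idempotent_at_fixed_point(self, hyper):
        design = _toy_design(n=60, m=3, seed=4, beta=[1.0, 0.0, 0.0])
        post = gr.fit_node(design, gr.Hyperparameters(elbo_tol=1e-12,
                                                      max_iter=5000))
        for _ in range(500):  # polish to machine-precision fixed point
            post = gr.cavi_sweep(design, post, hyper)
        again = gr.cavi_sweep(design, post, hyper)
        np.testing.assert_allclose(again.alpha, post.alpha, atol=1e-10)
        np.testing.assert_allclose(again.mu, post.mu, atol=1e-10)
        np.testing.assert_allclose(again.omega_rate, post.omega_rate, rtol=1e-10)

    def test_jit_and_numpy_paths_agree(self, hyper):
        design = _toy_design(n=50, m=6, q=2, seed=5, beta=[2, 0, 0, 1, 0, 0])
        a = gr.fit_node(design, hyper, use_jit=True)
        b = gr.fit_node(design, hyper, use_jit=False)
        np.testing.assert_allclose(a.alpha, b.alpha, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(a.elbo_trace, b.elbo_trace, rtol=1e-12)


class TestEnumerationOracle:
    """VB against exact spike/slab posteriors (all 2^m configurations) with
    slab precision, noise precision and inclusion probability held fixed."""

    @pytest.mark.parametrize("m,beta", [
        (2, [1.2, 0.0]),
        (4, [0.8, 0.0, -0.5, 0.0]),
        (6, [1.0, 0.0, 0.0, 0.3, 0.0, -0.8]),
    ])
    def test_vb_ranks_match_exact_pips(self, hyper, m, beta):
        design = _toy_design(n=80, m=m, seed=10 + m, beta=beta, orthogonal=True)
        tau, omega, pi0 = 1.0, 1.0, 0.2
        post = gr.fit_node(design, gr.Hyperparameters(elbo_tol=1e-10),
                           fix_tau=tau, fix_omega=omega, fix_pi=pi0)
        exact, _ = exact_spike_slab_pips(design.response, design.design,
                                         tau, omega, pi0)
        rho = spearmanr(post.alpha, exact).statistic
        assert rho == pytest.approx(1.0)

    def test_single_coefficient_vb_is_exact(self, hyper):
        # with m = 1 the mean-field family contains the true posterior
        design = _toy_design(n=40, m=1, seed=2, beta=[0.7])
        post = gr.fit_node(design, gr.Hyperparameters(elbo_tol=1e-12),
                           fix_tau=1.0, fix_omega=1.0, fix_pi=0.2)
        exact, _ = exact_spike_slab_pips(design.response, design.design,
                                         1.0, 1.0, 0.2)
        assert post.alpha[0] == pytest.approx(exact[0], abs=1e-6)

    def test_elbo_bounded_by_exact_evidence(self, hyper):
        design = _toy_design(n=30, m=2, seed=6, beta=[1.0, 0.0])
        post = gr.fit_node(design, hyper, fix_tau=2.0, fix_omega=1.5, fix_pi=0.2)
        elbo = gr.compute_elbo(design, post, hyper, fix_tau=2.0, fix_omega=1.5,
                               fix_pi=0.2)
        _, log_evidence = exact_spike_slab_pips(design.response, design.design,
                                                2.0, 1.5, 0.2)
        assert elbo <= log_evidence + 1e-9


class TestElbo:
    def test_monotone_over_sweeps(self, hyper):
        for seed in range(5):
            design = _toy_design(n=50, m=8, q=2, seed=seed,
                                 beta=[1, 0, 0, 0, -1, 0, 0, 0])
            post = gr.fit_node(design, hyper)
            trace = np.array(post.elbo_trace)
            assert np.all(np.diff(trace) >= -1e-6)

    def test_empty_design_closed_form(self, hyper):
        """A zero-regressor design's ELBO is the Gaussian-residual term plus
        the noise-precision Gamma entropy, both in closed form."""
        import math
        from scipy.special import digamma, gammaln
        design = _toy_design(n=25, m=0, seed=8)
        post = gr.fit_node(design, hyper)
        n = design.n
        yy = float(design.response @ design.response)
        c, d = n / 2.0 + 1.0, yy / 2.0
        expected = (0.5 * n * (digamma(c) - math.log(d))
                    - 0.5 * n * math.log(2 * math.pi) - c
                    + c - math.log(d) + gammaln(c) + (1 - c) * digamma(c))
        assert post.elbo_trace[-1] == pytest.approx(expected, rel=1e-12)
        assert post.converged


class TestFitNode:
    def test_pure_noise_shrinks(self):
        design = _toy_design(n=100, m=10, q=2, seed=9)
        post = gr.fit_node(design)
        assert post.alpha.mean() < 0.2

    def test_strong_signal_detected(self):
        design = _toy_design(n=200, m=10, q=2, seed=11,
                             beta=[3.0] + [0.0] * 9)
        post = gr.fit_node(design)
        assert post.alpha[0] > 0.95
        assert post.alpha[1:].mean() < 0.1

    def test_nonconvergence_flag_not_exception(self):
        design = _toy_design(n=60, m=6, seed=12, beta=[1, 0, 0, 1, 0, 0])
        post = gr.fit_node(design, gr.Hyperparameters(max_iter=1,
                                                      elbo_tol=1e-14))
        assert not post.converged
        assert len(post.elbo_trace) == 1


class TestFitGraph:
    def test_smallest_graph(self, hyper):
        rng = np.random.default_rng(13)
        y = rng.normal(size=(30, 2))
        fit = gr.fit_graph(y, np.ones((30, 1)), hyper=hyper)
        assert fit.p == 2
        assert fit.node_posteriors[0].index_map == [(1, 0)]
        assert fit.node_posteriors[1].index_map == [(0, 0)]

    def test_dag_mode_designs(self, hyper):
        rng = np.random.default_rng(14)
        y = rng.normal(size=(40, 3))
        x = rng.normal(size=(40, 2))
        fit = gr.fit_graph(y, x, hyper=hyper, mode="dag")
        assert fit.node_posteriors[0].m == 0
        assert fit.node_posteriors[2].m == 4  # 2 ancestors x q=2

    def test_index_maps_cover_all_ordered_pairs(self, homogeneous_case):
        _, fit, _ = homogeneous_case
        seen = {(i, j) for i, post in enumerate(fit.node_posteriors)
                for (j, _) in post.index_map}
        p = fit.p
        assert seen == {(i, j) for i in range(p) for j in range(p) if i != j}

    def test_intercept_only_reduces_to_neighborhood_selection(self, hyper):
        """With an intercept-only factor the fit equals a plain spike-and-slab
        neighborhood regression on the raw feature columns."""
        ds = gr.simulate_homogeneous(n=80, p=5, conn_prob=0.2, seed=15)
        fit = gr.fit_graph(ds.Y, ds.X, hyper=hyper)
        y_std, _, _ = standardize(ds.Y.values)
        design = build_node_design(y_std, np.ones((80, 1)), 0, "undirected")
        post = gr.fit_node(design, hyper)
        np.testing.assert_allclose(fit.node_posteriors[0].alpha, post.alpha,
                                   rtol=1e-12)

    def test_too_few_samples_raises(self):
        with pytest.raises(gr.InputError):
            gr.fit_graph(np.zeros((2, 3)), np.ones((2, 1)))

    def test_bit_identical_reruns(self):
        ds = gr.simulate_multicategory(n=60, p=6, conn_prob=0.1, seed=16)
        fit1 = gr.fit_graph(ds.Y, ds.X)
        fit2 = gr.fit_graph(ds.Y, ds.X)
        for a, b in zip(fit1.node_posteriors, fit2.node_posteriors):
            assert np.array_equal(a.alpha, b.alpha)
            assert np.array_equal(a.mu, b.mu)
            assert a.omega_rate == b.omega_rate
            assert a.elbo_trace == b.elbo_trace


class TestNullCalibration:
    def test_mean_inclusion_below_prior_on_null_data(self, hyper):
        rng = np.random.default_rng(17)
        y = rng.normal(size=(200, 10))
        x = np.column_stack([np.ones(200), rng.normal(size=200)])
        fit = gr.fit_graph(y, x, hyper=hyper)
        mean_alpha = np.concatenate(
            [post.alpha for post in fit.node_posteriors]).mean()
        assert mean_alpha < hyper.prior_inclusion
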