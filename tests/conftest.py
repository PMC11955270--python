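import numpy as np
import pytest

import graphreg as gr


@pytest.fixture(scope="session")
def hyper():
    return gr.Hyperparameters()


@pytest.fixture(scope="session")
def homogeneous_case():
    """Small homogeneous dataset with its fit and edge table (shared across
    tests; everything downstream of it is deterministic)."""
    ds = gr.simulate_homogeneous(n=120, p=10, conn_prob=0.08, seed=7)
    fit = gr.fit_graph(ds.Y, ds.X)
    table = gr.build_network(fit, np.ones((1, 1)), alpha=0.01,
                             covariate_ids=["all"])
    return ds, fit, table


@pytest.fixture(scope="session")
def multicategory_case():
    ds = gr.simulate_multicategory(n=120, p=12, groups=2, conn_prob=0.06, seed=3)
    fit = gr.fit_graph(ds.Y, ds.X)
    table = gr.build_network(fit, np.eye(2), alpha=0.01,
                             covariate_ids=["group1", "group2"])
    return ds, fit, table


def exact_spike_slab_pips(y, Z, tau, omega, pi0):
    """Exact posterior inclusion probabilities by enumerating all 2^m
    spike/slab configurations, with known slab precisions ``tau`` (per
    column), noise precision ``omega`` and prior inclusion ``pi0``.

    For a subset A of slab columns, y | A ~ N(0, Z_A T_A^{-1} Z_A' + I/omega).
    Returns (pips, log_evidence).
    """
    from itertools import product

    from scipy.special import logsumexp
    from scipy.stats import multivariate_normal

    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    n, m = Z.shape
    tau = np.broadcast_to(np.asarray(tau, float), (m,))
    log_joint, configs = [], []
    for s in product((0, 1), repeat=m):
        s = np.array(s, dtype=bool)
        cov = np.eye(n) / omega
        if s.any():
            Zs = Z[:, s]
            cov = cov + (Zs / tau[s]) @ Zs.T
        ll = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
        lp = s.sum() * np.log(pi0) + (m - s.sum()) * np.log1p(-pi0)
        log_joint.append(ll + lp)
        configs.append(s)
    log_joint = np.asarray(log_joint)
    log_evidence = logsumexp(log_joint)
    weights = np.exp(log_joint - log_evidence)
    pips = np.zeros(m)
    for w, s in zip(weights, configs):
        pips[s] += w
    return pips, float(log_evidence)
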