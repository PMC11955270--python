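"""Sample- and group-specific network construction from a fitted graphical
regression: posterior inclusion probabilities (PIPs), partial correlations,
and Bayesian-FDR edge selection.

For an evaluation covariate x (one row of intrinsic factors), the PIP of edge
(i, j) is a weighted mean of the per-factor inclusion probabilities with
weights (x_l * E[b_ijl])^2, and the partial correlation is the covariate-
modulated regression coefficient

    rho_ij(x) = sum_l x_l E[b_ijl s_ijl] = -omega_ij(x) / omega_ii

on the standardized scale (the fitted node-wise coefficient is
gamma_ij = -omega_ij/omega_ii, so this back-transform keeps the sign of the
true partial correlation).  Edges enter a network when their PIP clears a
Bayesian-FDR cutoff: the largest PIP-ranked prefix whose mean posterior
probability of being a false edge stays below the target level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError
from .model import GraphFit

__all__ = [
    "EdgeTable",
    "edge_pip",
    "edge_partial_correlation",
    "bayes_fdr_select",
    "symmetrize",
    "build_network",
    "apply_edge_filters",
]

EDGE_COLUMNS = ["i", "j", "covariate", "pip", "partial_correlation", "selected"]


@dataclass
class EdgeTable:
    """Per (edge, evaluation-covariate) records of PIP, partial correlation
    and selection flag.

    ``table`` columns: i, j (feature names; unordered pairs in undirected
    mode, ordered regressor->node pairs in dag mode), covariate (evaluation
    covariate id), pip, partial_correlation, selected.
    """

    table: pd.DataFrame
    fdr_level: float
    mode: str
    threshold: float = float("nan")
    covariates: pd.DataFrame | None = None   # original-scale evaluation rows

    def __post_init__(self):
        missing = [c for c in EDGE_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"edge table missing columns {missing}")

    def selected_edges(self, covariate=None) -> set[tuple[str, str]]:
        t = self.table
        if covariate is not None:
            t = t[t["covariate"] == covariate]
        return {(r.i, r.j) for r in t[t["selected"]].itertuples()}


def _node_edge_params(fit: GraphFit, i: int, j: int):
    """alpha and mu vectors (length q) for regressor j in node i's fit."""
    post = fit.node_posteriors[i]
    cols = [k for k, (jj, _) in enumerate(post.index_map) if jj == j]
    if not cols:
        raise InputError(
            f"node {fit.feature_names[j]!r} is not a regressor of "
            f"{fit.feature_names[i]!r} in {fit.mode} mode")
    cols = np.asarray(cols)
    return post.alpha[cols], post.mu[cols]


def edge_pip(fit: GraphFit, i: int, j: int, x) -> float:
    """Directed PIP of edge i <- j at evaluation covariate ``x`` (original
    factor scale): weighted mean of per-factor inclusion probabilities with
    weights (x_l E[b_l])^2; 0 when every weight vanishes (no evidence)."""
    xs = fit.standardize_factors(x)[0]
    alpha, mu = _node_edge_params(fit, i, j)
    w = (xs * mu) ** 2
    total = w.sum()
    if total == 0.0:
        return 0.0
    return float((w * alpha).sum() / total)


def edge_partial_correlation(fit: GraphFit, i: int, j: int, x,
                             clip: bool = False) -> float:
    """Directed partial-correlation estimate of edge i <- j at covariate ``x``
    (original factor scale): sum_l x_l alpha_l mu_l = -omega_ij(x)/omega_ii.

    ``clip`` truncates to [-1, 1] for reporting; the raw value is returned by
    default.
    """
    xs = fit.standardize_factors(x)[0]
    alpha, mu = _node_edge_params(fit, i, j)
    rho = float(xs @ (alpha * mu))
    if clip:
        rho = float(np.clip(rho, -1.0, 1.0))
    return rho


def bayes_fdr_select(pips, alpha: float):
    """Bayesian FDR selection: keep the largest PIP-descending prefix whose
    mean posterior false-edge probability, mean(1 - PIP), is <= alpha.

    Returns ``(flags, threshold)`` with flags in the input order and the
    realized PIP threshold (smallest selected PIP; inf when nothing is
    selected).
    """
    pips = np.asarray(pips, dtype=float)
    if pips.ndim != 1:
        raise InputError("pips must be one-dimensional")
    if np.any((pips < 0) | (pips > 1)):
        raise InputError("PIPs must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise InputError("FDR level must lie in (0, 1)")
    order = np.argsort(-pips, kind="stable")
    prefix_fdr = np.cumsum(1.0 - pips[order]) / np.arange(1, pips.size + 1)
    admissible = np.flatnonzero(prefix_fdr <= alpha)
    flags = np.zeros(pips.size, dtype=bool)
    if admissible.size == 0:
        return flags, float("inf")
    k = int(admissible[-1]) + 1
    flags[order[:k]] = True
    return flags, float(pips[order[k - 1]])


def symmetrize(table: EdgeTable, rule: str = "mean") -> EdgeTable:
    """Collapse directed edge records to one per unordered pair, replacing PIP
    and partial correlation with the mean (or max) of the two directions.
    No-op with a warning in dag mode."""
    if table.mode == "dag":
        warnings.warn("symmetrize is a no-op for dag-mode edge tables")
        return table
    if rule not in ("mean", "max"):
        raise InputError(f"unknown symmetrization rule {rule!r}")
    t = table.table.copy()
    a = t[["i", "j"]].to_numpy()
    lo = np.minimum(a[:, 0], a[:, 1])
    hi = np.maximum(a[:, 0], a[:, 1])
    t["i"], t["j"] = lo, hi
    agg = "mean" if rule == "mean" else "max"
    out = (t.groupby(["i", "j", "covariate"], as_index=False, sort=True)
            .agg(pip=("pip", agg), partial_correlation=("partial_correlation", agg),
                 selected=("selected", "any")))
    return EdgeTable(table=out[EDGE_COLUMNS], fdr_level=table.fdr_level,
                     mode=table.mode, threshold=table.threshold,
                     covariates=table.covariates)


def _directed_arrays(fit: GraphFit, xs: np.ndarray):
    """PIP and partial-correlation arrays of shape (R, p, p); entry [r, i, j]
    is the directed estimate i <- j at standardized covariate row r."""
    R, q = xs.shape
    p = fit.p
    pip = np.zeros((R, p, p))
    rho = np.zeros((R, p, p))
    for i, post in enumerate(fit.node_posteriors):
        if post.m == 0:
            continue
        regs = [j for (j, _) in post.index_map[::q]]
        a = post.alpha.reshape(-1, q)
        mu = post.mu.reshape(-1, q)
        w = (xs[:, None, :] * mu[None, :, :]) ** 2          # (R, nreg, q)
        den = w.sum(axis=2)
        num = (w * a[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore"):
            pip_i = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        rho_i = xs @ (a * mu).T                              # (R, nreg)
        pip[:, i, regs] = pip_i
        rho[:, i, regs] = rho_i
    return pip, rho


def build_network(fit: GraphFit, X_eval, alpha: float = 0.01,
                  covariate_ids=None, rule: str = "mean") -> EdgeTable:
    """Construct networks for each evaluation covariate row.

    ``X_eval`` holds rows of intrinsic factors on the original scale (one per
    group, subject or spatial location).  Directed estimates are computed for
    every (node, regressor) pair, symmetrized in undirected mode, and the
    Bayesian-FDR cutoff is applied jointly across all (pair x covariate)
    records.
    """
    X_eval = np.atleast_2d(np.asarray(X_eval, dtype=float))
    xs = fit.standardize_factors(X_eval)
    R = xs.shape[0]
    if covariate_ids is None:
        covariate_ids = [f"c{r + 1}" for r in range(R)]
    if len(covariate_ids) != R:
        raise InputError("covariate_ids length does not match X_eval rows")

    pip_d, rho_d = _directed_arrays(fit, xs)
    names = fit.feature_names
    p = fit.p
    if fit.mode == "undirected":
        iu, ju = np.triu_indices(p, k=1)
        pip = 0.5 * (pip_d[:, iu, ju] + pip_d[:, ju, iu])
        rho = 0.5 * (rho_d[:, iu, ju] + rho_d[:, ju, iu])
        if rule == "max":
            pip = np.maximum(pip_d[:, iu, ju], pip_d[:, ju, iu])
            rho = np.maximum(rho_d[:, iu, ju], rho_d[:, ju, iu])
        elif rule != "mean":
            raise InputError(f"unknown symmetrization rule {rule!r}")
    else:
        # ordered pairs (i, j) with j < i: regression of node i on ancestor j
        iu, ju = np.tril_indices(p, k=-1)
        pip = pip_d[:, iu, ju]
        rho = rho_d[:, iu, ju]

    npairs = iu.size
    flags, threshold = bayes_fdr_select(pip.ravel(), alpha)
    flags = flags.reshape(R, npairs)

    name_i = np.asarray(names, dtype=object)[iu]
    name_j = np.asarray(names, dtype=object)[ju]
    if fit.mode == "undirected":
        name_i, name_j = (np.minimum(name_i, name_j), np.maximum(name_i, name_j))
    table = pd.DataFrame({
        "i": np.tile(name_i, R),
        "j": np.tile(name_j, R),
        "covariate": np.repeat(np.asarray(covariate_ids, dtype=object), npairs),
        "pip": pip.ravel(),
        "partial_correlation": rho.ravel(),
        "selected": flags.ravel(),
    })
    cov = pd.DataFrame(X_eval, index=list(covariate_ids), columns=fit.factor_names)
    return EdgeTable(table=table, fdr_level=alpha, mode=fit.mode,
                     threshold=threshold, covariates=cov)


def apply_edge_filters(table: EdgeTable, min_abs_partial_correlation: float = None,
                       min_fraction_selected: float = None) -> EdgeTable:
    """Optional application-style post-filters on an edge table.

    ``min_abs_partial_correlation`` keeps pairs whose |rho| reaches the
    threshold in at least one covariate; ``min_fraction_selected`` keeps pairs
    selected in at least that fraction of covariates.  Filters compose.
    """
    t = table.table
    keep = pd.Series(True, index=pd.MultiIndex.from_frame(t[["i", "j"]]).unique())
    grouped = t.groupby(["i", "j"])
    if min_abs_partial_correlation is not None:
        ok = grouped["partial_correlation"].apply(
            lambda s: bool((s.abs() >= min_abs_partial_correlation).any()))
        keep &= ok
    if min_fraction_selected is not None:
        ok = grouped["selected"].mean() >= min_fraction_selected
        keep &= ok
    kept_pairs = set(keep[keep].index)
    mask = [(i, j) in kept_pairs for i, j in zip(t["i"], t["j"])]
    return EdgeTable(table=t[mask].reset_index(drop=True),
                     fdr_level=table.fdr_level, mode=table.mode,
                     threshold=table.threshold, covariates=table.covariates)
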