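"""Structure-recovery metrics (TPR/FPR/FDR/MCC, ROC-AUC) and the replication
harness that runs simulate -> fit -> network -> score over many replicates.

Conventions: FDR = 0 when nothing is selected; MCC = 0 when any factor of its
denominator vanishes; AUC is the rank (Mann-Whitney) statistic - the
probability that a random true edge outranks a random non-edge, ties counted
one half - which equals the area under the TPR/FPR curve swept over PIP
thresholds.  In per-subject scenarios (continuous factors, DAGs) metrics are
computed per subject and averaged; subjects whose truth is degenerate (no
positives or no negatives, possible with discrete factors) are skipped for
AUC only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import InputError
from .model import GraphFit, Hyperparameters, fit_graph
from .network import EdgeTable, build_network, edge_partial_correlation
from .simulate import SimulatedDataset, simulate_scenario, simulate_simpsons

__all__ = [
    "ConfusionCounts",
    "RecoveryStudy",
    "confusion",
    "metrics",
    "roc_auc",
    "evaluate_dataset",
    "replicate_study",
    "simpsons_demo",
]

METRIC_NAMES = ("tpr", "fpr", "fdr", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(truth, selected, universe) -> ConfusionCounts:
    """Standard confusion counts of ``selected`` against ``truth`` over the
    candidate-pair ``universe``."""
    truth, selected, universe = set(truth), set(selected), list(universe)
    uset = set(universe)
    if not truth <= uset:
        raise InputError("truth contains pairs outside the candidate universe")
    if not selected <= uset:
        raise InputError("selection contains pairs outside the candidate universe")
    tp = len(truth & selected)
    fp = len(selected - truth)
    fn = len(truth - selected)
    tn = len(uset) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> dict:
    """TPR, FPR, FDR and MCC with zero-denominator conventions (FDR = 0 when
    nothing is selected, MCC = 0 when its denominator vanishes)."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    fdr = fp / (fp + tp) if (fp + tp) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {"tpr": tpr, "fpr": fpr, "fdr": fdr, "mcc": mcc}


def _metrics_rows(truth: np.ndarray, selected: np.ndarray) -> dict:
    """Vectorized metrics over rows of boolean (rows, pairs) arrays; returns
    per-metric vectors."""
    truth = np.atleast_2d(truth)
    selected = np.atleast_2d(selected)
    tp = (truth & selected).sum(axis=1).astype(float)
    fp = (~truth & selected).sum(axis=1).astype(float)
    fn = (truth & ~selected).sum(axis=1).astype(float)
    tn = (~truth & ~selected).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpr = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        fpr = np.where(fp + tn > 0, fp / (fp + tn), 0.0)
        fdr = np.where(fp + tp > 0, fp / (fp + tp), 0.0)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(denom), 0.0)
    return {"tpr": tpr, "fpr": fpr, "fdr": fdr, "mcc": mcc}


def roc_auc(scores, truth_flags) -> float:
    """Area under the ROC curve of ``scores`` against binary ``truth_flags``,
    computed as the Mann-Whitney rank statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(truth_flags, dtype=bool)
    if scores.shape != flags.shape:
        raise InputError("scores and truth flags must have equal length")
    npos = int(flags.sum())
    nneg = flags.size - npos
    if npos == 0 or nneg == 0:
        raise InputError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[flags].sum() - npos * (npos + 1) / 2) / (npos * nneg))


# ---------------------------------------------------------------------------
# Dataset-level evaluation
# ---------------------------------------------------------------------------


def _edge_arrays(table: EdgeTable, n_rows: int):
    """(rows, pairs) pip / selected arrays; relies on build_network's
    deterministic covariate-major, pair-ordered layout."""
    t = table.table
    npairs = len(t) // n_rows
    pip = t["pip"].to_numpy().reshape(n_rows, npairs)
    sel = t["selected"].to_numpy().reshape(n_rows, npairs)
    return pip, sel


def _pair_truth_vector(edges: set, universe) -> np.ndarray:
    return np.array([pair in edges or (pair[1], pair[0]) in edges
                     for pair in universe])


def _row_aucs(pip: np.ndarray, truth: np.ndarray) -> list[float]:
    out = []
    for r in range(pip.shape[0]):
        pos = truth[r].sum()
        if pos == 0 or pos == truth.shape[1]:
            continue
        out.append(roc_auc(pip[r], truth[r]))
    return out


def evaluate_dataset(ds: SimulatedDataset, fit: GraphFit, alpha: float = 0.01) -> dict:
    """Score one fitted dataset against its ground truth.

    Group scenarios report pooled-over-groups metrics (primary) plus
    per-group averages; per-subject scenarios average subject-wise metrics.
    Also returns the built edge table.
    """
    universe = ds.pair_universe()
    if ds.truth_kind == "per_group":
        groups = len(ds.truth_edges)
        enc = ds.params.get("encoding", "indicator")
        if enc == "indicator":
            X_eval = np.eye(groups)
        else:
            X_eval = np.ones((groups, groups))
            X_eval[:, 1:] = np.eye(groups)[:, 1:]
        ids = [f"group{g + 1}" for g in range(groups)]
        table = build_network(fit, X_eval, alpha=alpha, covariate_ids=ids)
        pip, sel = _edge_arrays(table, groups)
        truth = np.vstack([_pair_truth_vector(ds.truth_edges[g], universe)
                           for g in range(groups)])
    elif ds.truth_kind == "global":
        X_eval = np.ones((1, 1)) if ds.X.q == 1 else ds.X.values[:1]
        table = build_network(fit, X_eval, alpha=alpha, covariate_ids=["all"])
        pip, sel = _edge_arrays(table, 1)
        truth = np.atleast_2d(_pair_truth_vector(ds.truth_edges[0], universe))
    elif ds.truth_kind == "per_subject":
        table = build_network(fit, ds.X.values, alpha=alpha,
                              covariate_ids=list(ds.Y.sample_ids))
        pip, sel = _edge_arrays(table, ds.n)
        truth = ds.subject_truth()
    else:
        raise InputError(f"unknown truth kind {ds.truth_kind!r}")

    rows = _metrics_rows(truth, sel)
    # average per-row metrics over rows whose true graph is non-empty: a
    # subject with no true edges (possible with discrete factors at x = 0)
    # has an undefined recovery problem, and both its truth and selection
    # are empty by construction
    keep = truth.sum(axis=1) > 0
    if not keep.any():
        keep = np.ones(truth.shape[0], dtype=bool)
    result = {name: float(np.mean(vals[keep])) for name, vals in rows.items()}
    aucs = _row_aucs(pip, truth)
    result["auc"] = float(np.mean(aucs)) if aucs else float("nan")

    if ds.truth_kind == "per_group":
        # primary metrics pool edges across the group networks
        pooled = metrics(ConfusionCounts(
            tp=int((truth & sel).sum()), fp=int((~truth & sel).sum()),
            tn=int((~truth & ~sel).sum()), fn=int((truth & ~sel).sum())))
        for name, val in list(result.items()):
            result[f"{name}_groupmean"] = val
        result.update(pooled)
        result["auc"] = roc_auc(pip.ravel(), truth.ravel())
    result["n_selected"] = int(sel.sum())
    result["edge_table"] = table
    return result


@dataclass
class RecoveryStudy:
    """Replicated structure-recovery summary."""

    scenario: str
    replicates: pd.DataFrame
    summary: pd.DataFrame
    alpha: float
    reps: int
    seed: int
    failures: list = field(default_factory=list)
    edge_tables: list = field(default_factory=list)


def replicate_study(scenario: str, reps: int = 50, alpha: float = 0.01,
                    hyper: Hyperparameters | None = None, seed: int = 0,
                    keep_tables: bool = False, **scenario_params) -> RecoveryStudy:
    """Replicate simulate -> fit -> build_network -> score and summarize.

    Each replicate r uses the derived seed (seed, r).  Per-replicate failures
    are recorded in ``failures`` and excluded from the summary rather than
    silently dropped.
    """
    hyper = hyper or Hyperparameters()
    rows, failures, tables = [], [], []
    for r in range(reps):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0]
                       % (2 ** 31))
        try:
            ds = simulate_scenario(scenario, seed=rep_seed, **scenario_params)
            fit = fit_graph(ds.Y, ds.X, hyper=hyper, mode=ds.mode)
            res = evaluate_dataset(ds, fit, alpha=alpha)
            table = res.pop("edge_table")
            if keep_tables:
                tables.append((ds, fit, table))
            res["replicate"] = r
            rows.append(res)
        except Exception as err:  # noqa: BLE001 - reported, not dropped
            failures.append((r, repr(err)))
    replicates = pd.DataFrame(rows)
    if len(replicates):
        numeric = replicates.drop(columns=["replicate"]).select_dtypes("number")
        summary = pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std(ddof=1)})
    else:
        summary = pd.DataFrame(columns=["mean", "sd"])
    return RecoveryStudy(scenario=scenario, replicates=replicates, summary=summary,
                         alpha=alpha, reps=reps, seed=seed, failures=failures,
                         edge_tables=tables)


def simpsons_demo(seed: int = 0, alpha: float = 0.01,
                  hyper: Hyperparameters | None = None) -> dict:
    """Fit the Simpson's-paradox dataset two ways and report the A-B partial
    correlation: per group under heterogeneous (group-indicator) fitting, and
    pooled under an intercept-only (homogeneous) fit."""
    hyper = hyper or Hyperparameters()
    ds = simulate_simpsons(seed=seed)
    het = fit_graph(ds.Y, ds.X, hyper=hyper)
    hom = fit_graph(ds.Y, ds.x_variants["intercept"], hyper=hyper)

    def sym_rho(fit, x):
        return 0.5 * (edge_partial_correlation(fit, 0, 1, x)
                      + edge_partial_correlation(fit, 1, 0, x))

    true_rho = [-ds.precisions[g][0, 1]
                / math.sqrt(ds.precisions[g][0, 0] * ds.precisions[g][1, 1])
                for g in (0, 1)]
    table = build_network(het, np.eye(2), alpha=alpha,
                          covariate_ids=["group1", "group2"])
    return {
        "rho_group1": sym_rho(het, (1.0, 0.0)),
        "rho_group2": sym_rho(het, (0.0, 1.0)),
        "rho_pooled": sym_rho(hom, (1.0,)),
        "true_rho_group1": true_rho[0],
        "true_rho_group2": true_rho[1],
        "edge_table": table,
        "dataset": ds,
    }
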