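"""File I/O: delimited feature/factor tables, pathway and region maps,
JSON serialization of fits and truths, and YAML run configuration.

All tables are plain text (comma or tab delimited, auto-detected), with a
header row of names and the sample id in the first column.  Numbers are
serialized at 17 significant digits so write-then-read round-trips are
lossless at double precision.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError
from .model import (FeatureMatrix, GraphFit, Hyperparameters, IntrinsicFactors,
                    NodePosterior)
from .network import EDGE_COLUMNS, EdgeTable
from .simulate import SimulatedDataset
from .summaries import PathwayMap, RegionLabels

__all__ = [
    "RunConfig",
    "load_config",
    "read_feature_table",
    "read_factor_table",
    "read_tables",
    "read_pathways",
    "read_regions",
    "write_graph_fit",
    "read_graph_fit",
    "write_edge_table",
    "read_edge_table",
    "write_dataset",
    "read_dataset",
]

FLOAT_FORMAT = "%.17g"
GRAPH_FIT_SCHEMA = 1


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file {path} does not exist")
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        sep = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise InputError(
            f"{path} has missing entries in columns {bad}; "
            "only complete cases are supported")
    return df


def read_feature_table(path) -> FeatureMatrix:
    """Read an n x p feature table (first column sample ids, header names)."""
    df = _read_delimited(path)
    return FeatureMatrix(df.to_numpy(dtype=float),
                         feature_names=[str(c) for c in df.columns],
                         sample_ids=[str(i) for i in df.index])


def read_factor_table(path, kinds=None) -> IntrinsicFactors:
    """Read an n x q intrinsic-factor table; column kinds are inferred
    (constant -> intercept, 0/1 -> indicator, otherwise continuous) unless
    given explicitly."""
    df = _read_delimited(path)
    return IntrinsicFactors(df.to_numpy(dtype=float),
                            factor_names=[str(c) for c in df.columns],
                            factor_kinds=list(kinds) if kinds is not None else None)


def read_tables(feature_path, factor_path, kinds=None):
    """Read and align feature and factor tables on sample ids; the factor
    rows are reordered to the feature order and id mismatches are errors."""
    Y = read_feature_table(feature_path)
    fdf = _read_delimited(factor_path)
    fdf.index = fdf.index.map(str)
    missing = [s for s in Y.sample_ids if s not in fdf.index]
    extra = [str(s) for s in fdf.index if s not in set(Y.sample_ids)]
    if missing or extra:
        raise InputError(
            f"sample ids do not match between tables; missing from factors: "
            f"{missing[:5]}, unknown in factors: {extra[:5]}")
    fdf = fdf.loc[Y.sample_ids]
    X = IntrinsicFactors(fdf.to_numpy(dtype=float),
                         factor_names=[str(c) for c in fdf.columns],
                         factor_kinds=list(kinds) if kinds is not None else None)
    return Y, X


def read_pathways(path, valid_features=None) -> PathwayMap:
    """Two-column delimited file: pathway, member."""
    df = _read_delimited_two_col(path, ("pathway", "member"))
    mapping = df.groupby("pathway")["member"].apply(set).to_dict()
    return PathwayMap(mapping, valid_features=valid_features)


def read_regions(path, valid_samples=None) -> RegionLabels:
    """Two-column delimited file: sample, region."""
    df = _read_delimited_two_col(path, ("sample", "region"))
    return RegionLabels(dict(zip(df["sample"], df["region"])),
                        valid_samples=valid_samples)


def _read_delimited_two_col(path, names) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file {path} does not exist")
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] != 2:
        raise InputError(f"{path} must have exactly two columns {names}")
    df.columns = names
    return df.astype(str)


# ---------------------------------------------------------------------------
# GraphFit JSON
# ---------------------------------------------------------------------------


def _arr(a) -> list:
    return np.asarray(a, dtype=float).tolist()


def write_graph_fit(fit: GraphFit, path):
    payload = {
        "schema": GRAPH_FIT_SCHEMA,
        "mode": fit.mode,
        "n": fit.n,
        "hyper": asdict(fit.hyper),
        "feature_names": fit.feature_names,
        "factor_names": fit.factor_names,
        "factor_kinds": fit.factor_kinds,
        "y_means": _arr(fit.y_means), "y_scales": _arr(fit.y_scales),
        "x_means": _arr(fit.x_means), "x_scales": _arr(fit.x_scales),
        "nodes": [{
            "alpha": _arr(post.alpha),
            "mu": _arr(post.mu),
            "sigma2": _arr(post.sigma2),
            "tau_shape": _arr(post.tau_shape), "tau_rate": _arr(post.tau_rate),
            "pi_a": _arr(post.pi_a), "pi_b": _arr(post.pi_b),
            "omega_shape": post.omega_shape, "omega_rate": post.omega_rate,
            "index_map": [[int(j), int(l)] for j, l in post.index_map],
            "elbo_trace": [float(v) for v in post.elbo_trace],
            "converged": bool(post.converged),
        } for post in fit.node_posteriors],
    }
    Path(path).write_text(json.dumps(payload))


def read_graph_fit(path) -> GraphFit:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != GRAPH_FIT_SCHEMA:
        raise InputError(f"unsupported graph-fit schema {payload.get('schema')!r}")
    posts = [NodePosterior(
        alpha=np.asarray(nd["alpha"], float), mu=np.asarray(nd["mu"], float),
        sigma2=np.asarray(nd["sigma2"], float),
        tau_shape=np.asarray(nd["tau_shape"], float),
        tau_rate=np.asarray(nd["tau_rate"], float),
        pi_a=np.asarray(nd["pi_a"], float), pi_b=np.asarray(nd["pi_b"], float),
        omega_shape=float(nd["omega_shape"]), omega_rate=float(nd["omega_rate"]),
        index_map=[(int(j), int(l)) for j, l in nd["index_map"]],
        elbo_trace=list(nd["elbo_trace"]), converged=bool(nd["converged"]),
    ) for nd in payload["nodes"]]
    return GraphFit(node_posteriors=posts, mode=payload["mode"],
                    hyper=Hyperparameters(**payload["hyper"]),
                    feature_names=payload["feature_names"],
                    factor_names=payload["factor_names"],
                    factor_kinds=payload["factor_kinds"],
                    y_means=np.asarray(payload["y_means"], float),
                    y_scales=np.asarray(payload["y_scales"], float),
                    x_means=np.asarray(payload["x_means"], float),
                    x_scales=np.asarray(payload["x_scales"], float),
                    n=int(payload["n"]))


# ---------------------------------------------------------------------------
# EdgeTable CSV + JSON sidecar
# ---------------------------------------------------------------------------


def write_edge_table(table: EdgeTable, path):
    path = Path(path)
    table.table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    meta = {"fdr_level": table.fdr_level, "mode": table.mode,
            "threshold": table.threshold}
    if table.covariates is not None:
        meta["covariates"] = {
            "ids": [str(i) for i in table.covariates.index],
            "columns": [str(c) for c in table.covariates.columns],
            "values": _arr(table.covariates.to_numpy()),
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_edge_table(path) -> EdgeTable:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path} is not an edge table; missing {missing}")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    cov = None
    if "covariates" in meta:
        c = meta["covariates"]
        cov = pd.DataFrame(c["values"], index=c["ids"], columns=c["columns"])
    return EdgeTable(table=df, fdr_level=meta.get("fdr_level", float("nan")),
                     mode=meta.get("mode", "undirected"),
                     threshold=meta.get("threshold", float("nan")),
                     covariates=cov)


# ---------------------------------------------------------------------------
# Simulated datasets
# ---------------------------------------------------------------------------


def write_dataset(ds: SimulatedDataset, directory):
    """Write features.csv, factors.csv and truth.json into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ds.Y.values, index=ds.Y.sample_ids,
                 columns=ds.Y.feature_names).to_csv(
        directory / "features.csv", float_format=FLOAT_FORMAT)
    pd.DataFrame(ds.X.values, index=ds.Y.sample_ids,
                 columns=ds.X.factor_names).to_csv(
        directory / "factors.csv", float_format=FLOAT_FORMAT)
    truth = {
        "scenario": ds.scenario, "seed": ds.seed, "mode": ds.mode,
        "truth_kind": ds.truth_kind, "params": ds.params,
        "factor_kinds": ds.X.factor_kinds,
        "truth_edges": ([sorted([int(a), int(b)] for a, b in s)
                         for s in ds.truth_edges]
                        if ds.truth_edges is not None else None),
        "group_of": (_arr(ds.group_of) if ds.group_of is not None else None),
        "beta": (_arr(ds.beta) if ds.beta is not None else None),
        "precisions": ([_arr(m) for m in ds.precisions]
                       if ds.precisions is not None else None),
    }
    (directory / "truth.json").write_text(json.dumps(truth))


def read_dataset(directory) -> SimulatedDataset:
    directory = Path(directory)
    Y, X = read_tables(directory / "features.csv", directory / "factors.csv")
    truth = json.loads((directory / "truth.json").read_text())
    X.factor_kinds = truth["factor_kinds"]
    return SimulatedDataset(
        Y=Y, X=X, scenario=truth["scenario"], seed=truth["seed"],
        mode=truth["mode"], truth_kind=truth["truth_kind"],
        truth_edges=([{(int(a), int(b)) for a, b in s}
                      for s in truth["truth_edges"]]
                     if truth["truth_edges"] is not None else None),
        group_of=(np.asarray(truth["group_of"], int)
                  if truth["group_of"] is not None else None),
        beta=(np.asarray(truth["beta"], float)
              if truth["beta"] is not None else None),
        precisions=([np.asarray(m, float) for m in truth["precisions"]]
                    if truth["precisions"] is not None else None),
        params=truth["params"])


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration shared by the command-line pipeline."""

    features: str | None = None
    factors: str | None = None
    pathways: str | None = None
    regions: str | None = None
    mode: str = "undirected"
    a_tau: float = 0.005
    b_tau: float = 0.005
    a_pi: float = 1.0
    b_pi: float = 4.0
    elbo_tol: float = 1e-4
    max_iter: int = 1000
    alpha: float = 0.01
    scenario: str | None = None
    scenario_params: dict = field(default_factory=dict)
    reps: int = 50
    seed: int = 0
    outdir: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InputError("alpha must lie in (0, 1)")

    def hyperparameters(self) -> Hyperparameters:
        return Hyperparameters(a_tau=self.a_tau, b_tau=self.b_tau,
                               a_pi=self.a_pi, b_pi=self.b_pi,
                               elbo_tol=self.elbo_tol, max_iter=self.max_iter,
                               seed=self.seed)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig with precedence: explicit overrides > YAML file >
    defaults.  Overrides with value None are ignored."""
    data = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise InputError(f"config file {path} must hold a mapping")
        unknown = set(loaded) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys {sorted(unknown)}")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
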