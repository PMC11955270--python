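"""Downstream network summaries: hub detection via connectivity degrees,
pathway connectivity scores, and region-weighted spatial summaries.

All operations consume an :class:`~graphreg.network.EdgeTable`; "significant"
always means the table's Bayesian-FDR selection flags.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd

from .exceptions import InputError
from .network import EdgeTable

__all__ = [
    "PathwayMap",
    "RegionLabels",
    "connectivity_degree",
    "connectivity_score",
    "region_weighted_partial_correlation",
    "weighted_connectivity_degree",
    "weighted_connectivity_degrees",
]


class PathwayMap(dict):
    """pathway name -> set of member features; singleton pathways rejected."""

    def __init__(self, mapping, valid_features=None):
        super().__init__()
        for name, members in dict(mapping).items():
            members = set(members)
            if len(members) < 2:
                raise InputError(f"pathway {name!r} has fewer than 2 members")
            if valid_features is not None:
                unknown = members - set(valid_features)
                if unknown:
                    raise InputError(
                        f"pathway {name!r} has unknown members {sorted(unknown)}")
            self[name] = members


class RegionLabels(dict):
    """sample/covariate id -> region label."""

    def __init__(self, mapping, valid_samples=None):
        super().__init__(dict(mapping))
        if valid_samples is not None:
            unknown = set(self) - set(valid_samples)
            if unknown:
                raise InputError(f"region labels refer to unknown samples "
                                 f"{sorted(unknown)[:5]}")

    def regions(self):
        return sorted(set(self.values()))

    def samples_in(self, region):
        return [s for s, r in self.items() if r == region]


def _nodes_of(edges: EdgeTable) -> set:
    return set(edges.table["i"]) | set(edges.table["j"])


def _pick_covariate(edges: EdgeTable, covariate):
    t = edges.table
    if covariate is not None:
        if covariate not in set(t["covariate"]):
            raise InputError(f"unknown covariate {covariate!r}")
        return t[t["covariate"] == covariate]
    if t["covariate"].nunique() > 1:
        raise InputError("edge table has several covariates; pass covariate=...")
    return t


def connectivity_degree(edges: EdgeTable, node, covariate=None) -> float:
    """Sum of |partial correlation| over the node's selected edges."""
    if node not in _nodes_of(edges):
        raise InputError(f"unknown node {node!r}")
    t = _pick_covariate(edges, covariate)
    t = t[t["selected"] & ((t["i"] == node) | (t["j"] == node))]
    return float(t["partial_correlation"].abs().sum())


def connectivity_score(edges: EdgeTable, members, covariate=None) -> float:
    """Selected within-pathway edge count / C(|pathway|, 2)."""
    members = set(members)
    if len(members) < 2:
        raise InputError("a pathway needs at least 2 members")
    t = _pick_covariate(edges, covariate)
    inside = t["selected"] & t["i"].isin(members) & t["j"].isin(members)
    return float(inside.sum() / comb(len(members), 2))


def _pair_rows(edges: EdgeTable, i, j) -> pd.DataFrame:
    t = edges.table
    rows = t[((t["i"] == i) & (t["j"] == j)) | ((t["i"] == j) & (t["j"] == i))]
    if rows.empty:
        raise InputError(f"no records for pair ({i!r}, {j!r})")
    return rows.set_index("covariate")


def region_weighted_partial_correlation(edges: EdgeTable, regions: RegionLabels,
                                        i, j) -> pd.Series:
    """PIP-weighted regional average of per-sample partial correlations:
    rho_hat(region) = sum_{samples in region} rho * PIP / n_region."""
    rows = _pair_rows(edges, i, j)
    out = {}
    for region in regions.regions():
        samples = regions.samples_in(region)
        if not samples:
            raise InputError(f"region {region!r} is empty")
        missing = [s for s in samples if s not in rows.index]
        if missing:
            raise InputError(f"no edge records for samples {missing[:5]} "
                             f"in region {region!r}")
        sub = rows.loc[samples]
        out[region] = float((sub["partial_correlation"] * sub["pip"]).sum()
                            / len(samples))
    return pd.Series(out).sort_index()


def weighted_connectivity_degrees(edges: EdgeTable, regions: RegionLabels,
                                  rescale: bool = False) -> pd.DataFrame:
    """Per-node, per-region sum of |region-weighted partial correlations|.

    With ``rescale`` each region's degrees are divided by the maximum across
    nodes (all-zero regions stay zero), so the top hub gets degree 1.
    """
    t = edges.table
    nodes = sorted(_nodes_of(edges))
    sample_region = pd.Series({s: regions[s] for s in regions})
    cov_region = t["covariate"].map(sample_region)
    if cov_region.isna().any():
        raise InputError("edge table has covariates without region labels")
    work = t.assign(region=cov_region, wrho=t["partial_correlation"] * t["pip"])
    counts = sample_region.value_counts()
    # region-weighted rho per (pair, region), then |.| summed per node
    per_pair = (work.groupby(["i", "j", "region"])["wrho"].sum()
                    .div(counts, level="region").abs()
                    .rename("wrho").reset_index())
    out = pd.DataFrame(0.0, index=nodes, columns=sorted(counts.index))
    for _, row in per_pair.iterrows():
        out.loc[row["i"], row["region"]] += row["wrho"]
        out.loc[row["j"], row["region"]] += row["wrho"]
    if rescale:
        for region in out.columns:
            peak = out[region].max()
            if peak > 0:
                out[region] = out[region] / peak
    return out


def weighted_connectivity_degree(edges: EdgeTable, regions: RegionLabels,
                                 node, rescale: bool = False) -> pd.Series:
    """Region-weighted connectivity degree of one node (see
    :func:`weighted_connectivity_degrees`)."""
    table = weighted_connectivity_degrees(edges, regions, rescale=rescale)
    if node not in table.index:
        raise InputError(f"unknown node {node!r}")
    return table.loc[node]
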