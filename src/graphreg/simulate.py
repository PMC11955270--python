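"""Synthetic data generators with known ground-truth graphs.

Five generators cover the benchmark settings used throughout the package:

* ``simulate_multicategory`` - samples split into G groups; group precision
  matrices differ by a 3-edge swap of an Erdos-Renyi base graph.
* ``simulate_continuous``   - subject-specific precision matrices whose
  off-diagonals are linear in two Uniform(-1, 1) intrinsic factors.
* ``simulate_homogeneous``  - one shared Erdos-Renyi precision matrix,
  intercept-only factors (positive control).
* ``simulate_dag``          - directed acyclic generation with covariate-
  modulated parent effects.
* ``simulate_simpsons``     - a 3-node, 2-group construction in which the
  pooled association between two nodes contradicts both group-wise ones.

Every generator is reproducible bit-for-bit from its parameters and seed, and
every stored precision matrix is symmetric positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .model import FeatureMatrix, IntrinsicFactors

__all__ = [
    "SimulatedDataset",
    "erdos_renyi_precision",
    "make_positive_definite",
    "perturb_graph",
    "simulate_multicategory",
    "simulate_continuous",
    "simulate_homogeneous",
    "simulate_dag",
    "simulate_simpsons",
    "simulate_scenario",
]

# Joint positive definiteness across all subjects in the continuous scenario
# is roughly a 1-in-8,000 event per draw at p=33 (the support must form a
# node-disjoint matching), so the redraw cap must sit far above the expected
# redraw count.
PD_REDRAW_CAP = 200_000


@dataclass
class SimulatedDataset:
    """A generated dataset plus its ground truth.

    ``truth_kind`` is ``per_group`` (one edge set per group, with ``group_of``
    mapping samples to groups), ``global`` (one edge set), or ``per_subject``
    (edges derived from the coefficient array ``beta``; use
    ``subject_truth()``).  Edge sets contain 0-based index pairs, (i, j) with
    i < j for undirected scenarios and regressor-ordered (i, j), j < i, for
    the dag scenario.
    """

    Y: FeatureMatrix
    X: IntrinsicFactors
    scenario: str
    seed: int
    mode: str = "undirected"
    truth_kind: str = "global"
    truth_edges: list[set[tuple[int, int]]] | None = None
    group_of: np.ndarray | None = None
    beta: np.ndarray | None = None          # (p, p, q) coefficient array
    precisions: list[np.ndarray] | None = None
    params: dict = field(default_factory=dict)
    x_variants: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.Y.n

    @property
    def p(self) -> int:
        return self.Y.p

    def pair_universe(self) -> list[tuple[int, int]]:
        p = self.p
        if self.mode == "dag":
            return [(i, j) for i in range(p) for j in range(i)]
        return [(i, j) for i in range(p) for j in range(i + 1, p)]

    def subject_truth(self) -> np.ndarray:
        """(n, n_pairs) boolean edge support per subject: edge (i, j) is real
        for subject x iff its covariate-modulated coefficient
        sum_l beta_ijl x_l is nonzero."""
        if self.beta is None:
            raise InputError(f"scenario {self.scenario!r} has no coefficient truth")
        pairs = self.pair_universe()
        xv = self.X.values
        support = np.empty((self.n, len(pairs)), dtype=bool)
        for k, (i, j) in enumerate(pairs):
            support[:, k] = xv @ self.beta[i, j, :] != 0.0
        return support


# ---------------------------------------------------------------------------
# Precision-matrix building blocks
# ---------------------------------------------------------------------------


def _edge_weights(rng: np.random.Generator, size: int) -> np.ndarray:
    """Magnitudes uniform on [0.5, 1] with random sign: Uniform([-1,-0.5] U [0.5,1])."""
    mags = rng.uniform(0.5, 1.0, size=size)
    signs = rng.choice((-1.0, 1.0), size=size)
    return mags * signs


def make_positive_definite(M: np.ndarray, step: float = 0.1) -> np.ndarray:
    """Add step * k * I for the smallest integer k >= 0 that makes the matrix
    positive definite; off-diagonals are untouched."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or not np.allclose(M, M.T):
        raise InputError("make_positive_definite requires a symmetric matrix")
    out = M.copy()
    eye = np.eye(M.shape[0])
    while np.linalg.eigvalsh(out)[0] <= 0:
        out = out + step * eye
    return out


def _is_pd(M: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(M)
        return True
    except np.linalg.LinAlgError:
        return False


def erdos_renyi_precision(p: int, conn_prob: float, rng: np.random.Generator):
    """Erdos-Renyi precision matrix: each pair connected with probability
    ``conn_prob``; connected off-diagonals drawn Uniform([-1,-0.5] U [0.5,1]),
    unit diagonal, then ridge-shifted to positive definiteness.

    Returns ``(precision, edges)`` with edges a set of (i, j), i < j.
    """
    if not 0 < conn_prob < 1:
        raise InputError("connection probability must lie in (0, 1)")
    iu, ju = np.triu_indices(p, k=1)
    connected = rng.random(iu.size) < conn_prob
    weights = np.where(connected, _edge_weights(rng, iu.size), 0.0)
    M = np.eye(p)
    M[iu, ju] = weights
    M[ju, iu] = weights
    edges = {(int(i), int(j)) for i, j, c in zip(iu, ju, connected) if c}
    return make_positive_definite(M), edges


def perturb_graph(precision: np.ndarray, edges: set, rng: np.random.Generator):
    """Swap 3 uniformly chosen edges for 3 uniformly chosen non-edges, redraw
    the new edges' weights, reset the diagonal to 1 and re-PD-ify.

    Returns ``(new_precision, new_edges)``.
    """
    precision = np.asarray(precision, dtype=float)
    p = precision.shape[0]
    all_pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    absent = sorted(set(all_pairs) - set(edges))
    present = sorted(edges)
    if len(present) < 3 or len(absent) < 3:
        raise InputError("perturbation needs at least 3 edges and 3 non-edges")
    drop_idx = rng.choice(len(present), size=3, replace=False)
    add_idx = rng.choice(len(absent), size=3, replace=False)
    raw = precision.copy()
    np.fill_diagonal(raw, 1.0)
    new_edges = set(edges)
    for k in sorted(drop_idx):
        i, j = present[k]
        raw[i, j] = raw[j, i] = 0.0
        new_edges.discard((i, j))
    new_weights = _edge_weights(rng, 3)
    for w, k in zip(new_weights, sorted(add_idx)):
        i, j = absent[k]
        raw[i, j] = raw[j, i] = w
        new_edges.add((i, j))
    return make_positive_definite(raw), new_edges


def _solve_lt(L: np.ndarray, eps: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular
    return solve_triangular(L, eps.T, lower=True, trans="T").T


def _sample_mvn(rng: np.random.Generator, precision: np.ndarray,
                size: int) -> np.ndarray:
    """Draw N(0, precision^{-1}) rows via the Cholesky factor of the
    precision: with precision = L L', solving L' z = eps yields the target
    covariance."""
    L = np.linalg.cholesky(precision)
    eps = rng.standard_normal((size, precision.shape[0]))
    return _solve_lt(L, eps)


# ---------------------------------------------------------------------------
# Scenario generators
# ---------------------------------------------------------------------------


def _group_sizes(n: int, groups: int) -> list[int]:
    base = n // groups
    extra = n % groups
    return [base + (1 if g < extra else 0) for g in range(groups)]


def simulate_multicategory(n: int = 151, p: int = 33, groups: int = 2,
                           conn_prob: float = 0.02, seed: int = 0,
                           encoding: str = "indicator") -> SimulatedDataset:
    """Multi-category graphs: samples split as evenly as possible into
    ``groups`` groups; the first group's precision is Erdos-Renyi and each
    later group differs from its predecessor by a 3-edge swap.  Intrinsic
    factors are group indicators (default) or intercept + (G-1) indicators."""
    if groups < 2:
        raise InputError("need at least 2 groups")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    # first group must admit the 3-in/3-out perturbation
    while True:
        omega, edges = erdos_renyi_precision(p, conn_prob, rng)
        npairs = p * (p - 1) // 2
        if 3 <= len(edges) <= npairs - 3:
            break
    precisions, truths = [omega], [edges]
    for _ in range(groups - 1):
        omega, edges = perturb_graph(precisions[-1], truths[-1], rng)
        precisions.append(omega)
        truths.append(edges)

    sizes = _group_sizes(n, groups)
    blocks, group_of = [], []
    for g, size in enumerate(sizes):
        blocks.append(_sample_mvn(rng, precisions[g], size))
        group_of.extend([g] * size)
    Y = FeatureMatrix(np.vstack(blocks))
    group_of = np.asarray(group_of)

    if encoding == "indicator":
        xv = np.zeros((n, groups))
        xv[np.arange(n), group_of] = 1.0
        names = [f"group{g + 1}" for g in range(groups)]
        kinds = ["indicator"] * groups
    elif encoding == "intercept":
        xv = np.ones((n, groups))
        for g in range(1, groups):
            xv[:, g] = (group_of == g).astype(float)
        names = ["intercept"] + [f"group{g + 1}" for g in range(1, groups)]
        kinds = ["intercept"] + ["indicator"] * (groups - 1)
    else:
        raise InputError(f"unknown encoding {encoding!r}")
    X = IntrinsicFactors(xv, factor_names=names, factor_kinds=kinds)
    return SimulatedDataset(Y=Y, X=X, scenario="multicategory", seed=seed,
                            truth_kind="per_group", truth_edges=truths,
                            group_of=group_of, precisions=precisions,
                            params=dict(n=n, p=p, groups=groups,
                                        conn_prob=conn_prob, encoding=encoding))


def simulate_continuous(n: int = 151, p: int = 33, q: int = 2,
                        frac_nonzero: float = 0.02, seed: int = 0) -> SimulatedDataset:
    """Continuously varying graphs: a symmetric sparse coefficient array beta,
    intrinsic factors Uniform(-1, 1), and subject-specific precisions
    omega_n[i, j] = sum_l beta_ijl x_nl with unit diagonal.  The whole draw is
    repeated until every subject's precision is positive definite.

    About ``frac_nonzero`` of the C(p, 2) pairs carry a +/-1 coefficient on
    one uniformly chosen factor.  Joint positive definiteness over all n
    subjects effectively restricts the support to a node-disjoint matching
    with one active factor per pair (a node with two incident covariate-
    driven edges fails PD for some subject with overwhelming probability),
    so denser slot-level supports would make the rejection loop diverge.
    """
    if q < 1:
        raise InputError("need at least one intrinsic factor")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    iu, ju = np.triu_indices(p, k=1)
    npairs = iu.size
    ncoef = (max(1, round(frac_nonzero * npairs))
             if frac_nonzero > 0 else 0)
    eye = np.eye(p)
    for _ in range(PD_REDRAW_CAP):
        pairs_chosen = rng.choice(npairs, size=ncoef, replace=False)
        factors = rng.integers(0, q, size=ncoef)
        values = rng.choice((-1.0, 1.0), size=ncoef)
        entries = [(int(iu[int(k)]), int(ju[int(k)]), int(l), float(v))
                   for k, l, v in zip(pairs_chosen, factors, values)]
        xv = rng.uniform(-1.0, 1.0, size=(n, q))
        # check subjects one by one, bailing at the first non-PD precision
        ok = True
        for r in range(n):
            M = eye.copy()
            for i, j, l, v in entries:
                w = v * xv[r, l]
                M[i, j] += w
                M[j, i] += w
            if not _is_pd(M):
                ok = False
                break
        if ok:
            beta = np.zeros((p, p, q))
            for i, j, l, v in entries:
                beta[i, j, l] = beta[j, i, l] = v
            precisions = np.tensordot(xv, beta, axes=([1], [2])) + eye
            break
    else:
        raise InputError(
            f"no jointly positive-definite draw within {PD_REDRAW_CAP} attempts")
    rows = np.empty((n, p))
    for r in range(n):
        rows[r] = _sample_mvn(rng, precisions[r], 1)[0]
    Y = FeatureMatrix(rows)
    X = IntrinsicFactors(xv, factor_names=[f"X{l + 1}" for l in range(q)],
                         factor_kinds=["continuous"] * q)
    return SimulatedDataset(Y=Y, X=X, scenario="continuous", seed=seed,
                            truth_kind="per_subject", beta=beta,
                            precisions=list(precisions),
                            params=dict(n=n, p=p, q=q, frac_nonzero=frac_nonzero))


def simulate_homogeneous(n: int = 151, p: int = 33, conn_prob: float = 0.02,
                         seed: int = 0) -> SimulatedDataset:
    """Homogeneous graphs: one Erdos-Renyi precision shared by all samples,
    intercept-only intrinsic factor (positive-control setting)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    omega, edges = erdos_renyi_precision(p, conn_prob, rng)
    Y = FeatureMatrix(_sample_mvn(rng, omega, n))
    X = IntrinsicFactors(np.ones((n, 1)), factor_names=["intercept"],
                         factor_kinds=["intercept"])
    return SimulatedDataset(Y=Y, X=X, scenario="homogeneous", seed=seed,
                            truth_kind="global", truth_edges=[edges],
                            precisions=[omega],
                            params=dict(n=n, p=p, conn_prob=conn_prob))


def simulate_dag(n: int = 500, p: int = 50, q: int = 2, effect: float = 3.0,
                 frac_nonzero: float = 0.02, factor_kinds=None,
                 seed: int = 0) -> SimulatedDataset:
    """Directed acyclic generation with a known topological order.

    Continuous factors are Uniform(0, 1), discrete ones Bernoulli(0.5).  For
    each factor, about ``frac_nonzero`` of the ancestor pairs (j < i) carry a
    coefficient equal to ``effect``.  Node 1 is standard normal; node i is
    drawn around the covariate-modulated sum of its standardized ancestors
    with unit noise.  When ``factor_kinds`` is omitted and q > 2, 70% of the
    factors are continuous.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    if factor_kinds is None:
        if q <= 2:
            factor_kinds = ("continuous",) * q
        else:
            ncont = int(round(0.7 * q))
            factor_kinds = ("continuous",) * ncont + ("indicator",) * (q - ncont)
    factor_kinds = tuple(factor_kinds)
    if len(factor_kinds) != q:
        raise InputError("factor_kinds length must equal q")
    xv = np.empty((n, q))
    for l, kind in enumerate(factor_kinds):
        if kind == "continuous":
            xv[:, l] = rng.uniform(0.0, 1.0, size=n)
        elif kind == "indicator":
            xv[:, l] = rng.integers(0, 2, size=n).astype(float)
        else:
            raise InputError(f"dag factors must be continuous or indicator, "
                             f"got {kind!r}")

    pairs = [(i, j) for i in range(p) for j in range(i)]      # ancestor pairs j < i
    npairs = len(pairs)
    ncoef = (max(1, round(frac_nonzero * npairs))
             if frac_nonzero > 0 else 0)
    beta = np.zeros((p, p, q))
    for l in range(q):
        chosen = rng.choice(npairs, size=ncoef, replace=False)
        for k in chosen:
            i, j = pairs[int(k)]
            beta[i, j, l] = effect

    Y = np.empty((n, p))
    Y[:, 0] = rng.standard_normal(n)
    for i in range(1, p):
        prior = Y[:, :i]
        tilde = (prior - prior.mean(axis=0)) / prior.std(axis=0, ddof=1)
        coef = xv @ beta[i, :i, :].T                          # (n, i)
        mean = (coef * tilde).sum(axis=1)
        Y[:, i] = mean + rng.standard_normal(n)
    X = IntrinsicFactors(xv, factor_names=[f"X{l + 1}" for l in range(q)],
                         factor_kinds=list(factor_kinds))
    return SimulatedDataset(Y=FeatureMatrix(Y), X=X, scenario="dag", seed=seed,
                            mode="dag", truth_kind="per_subject", beta=beta,
                            params=dict(n=n, p=p, q=q, effect=effect,
                                        frac_nonzero=frac_nonzero,
                                        factor_kinds=list(factor_kinds)))


def simulate_simpsons(seed: int = 0, n: int = 200) -> SimulatedDataset:
    """Simpson's-paradox construction: two equal groups of 3-node Gaussians.

    Group 1 precision has omega_12 in [0.5, 1] (negative true partial
    correlation between nodes 1 and 2), omega_13 in [-1, -0.5], omega_23 = 0;
    group 2 reverses the roles (omega_12 in [-1, -0.5], omega_23 in [0.5, 1],
    omega_13 = 0).  Both are redrawn until positive definite.  ``X`` holds the
    group indicators; ``x_variants['intercept']`` the homogeneous pooled
    encoding.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    for _ in range(PD_REDRAW_CAP):
        o1 = np.eye(3)
        o1[0, 1] = o1[1, 0] = rng.uniform(0.5, 1.0)
        o1[0, 2] = o1[2, 0] = rng.uniform(-1.0, -0.5)
        o2 = np.eye(3)
        o2[0, 1] = o2[1, 0] = rng.uniform(-1.0, -0.5)
        o2[1, 2] = o2[2, 1] = rng.uniform(0.5, 1.0)
        if _is_pd(o1) and _is_pd(o2):
            break
    else:
        raise InputError("no positive-definite draw for the Simpson construction")
    half = n // 2
    sizes = [half, n - half]
    edges = [{(0, 1), (0, 2)}, {(0, 1), (1, 2)}]
    rows = np.vstack([_sample_mvn(rng, o1, sizes[0]),
                      _sample_mvn(rng, o2, sizes[1])])
    group_of = np.repeat([0, 1], sizes)
    xv = np.zeros((n, 2))
    xv[np.arange(n), group_of] = 1.0
    X = IntrinsicFactors(xv, factor_names=["group1", "group2"],
                         factor_kinds=["indicator", "indicator"])
    intercept = IntrinsicFactors(np.ones((n, 1)), factor_names=["intercept"],
                                 factor_kinds=["intercept"])
    Y = FeatureMatrix(rows, feature_names=["A", "B", "C"])
    return SimulatedDataset(Y=Y, X=X, scenario="simpsons", seed=seed,
                            truth_kind="per_group", truth_edges=edges,
                            group_of=group_of, precisions=[o1, o2],
                            params=dict(n=n),
                            x_variants={"intercept": intercept})


SCENARIOS = {
    "multicategory": simulate_multicategory,
    "continuous": simulate_continuous,
    "homogeneous": simulate_homogeneous,
    "dag": simulate_dag,
    "simpsons": simulate_simpsons,
}


def simulate_scenario(scenario: str, seed: int = 0, **params) -> SimulatedDataset:
    """Dispatch a generator by scenario name."""
    if scenario not in SCENARIOS:
        raise InputError(f"unknown scenario {scenario!r}; "
                         f"choose from {sorted(SCENARIOS)}")
    return SCENARIOS[scenario](seed=seed, **params)
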