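"""Community-environment multivariate toolbox.

Square-root transformation of abundances, dissimilarity matrices
(Euclidean, Bray-Curtis, normalised Euclidean), Ward agglomerative
clustering with similarity-level cuts, Spearman correlation screens,
and the two matrix-correlation procedures used in community
bioassessment:

- RELATE: a Mantel-type permutation test of the Spearman rank
  correlation between two dissimilarity matrices over the same samples.
- BIOENV: exhaustive search over environmental-variable subsets for the
  subset whose (normalised Euclidean) sample dissimilarities best
  rank-correlate with a fixed biotic dissimilarity matrix.

Default metric choices (Bray-Curtis on square-root abundances for the
biota, Euclidean on standardised variables for the environment) follow
the documented defaults of the PRIMER family of routines; both are
parameters. Condensed vectors use row-major upper-triangle order
(i < j) throughout.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

from .types import CommunityMatrix, MatrixError, SaprolensError

__all__ = [
    "sqrt_transform",
    "DistanceMatrix",
    "distance_matrix",
    "Dendrogram",
    "ward_cluster",
    "cut_at_similarity",
    "spearman_screen",
    "MatrixCorrelationResult",
    "relate",
    "BioenvResult",
    "bioenv",
]

METRICS = ("euclidean", "bray-curtis", "normalized-euclidean")


def sqrt_transform(matrix: CommunityMatrix) -> CommunityMatrix:
    """Element-wise square root (down-weights very abundant taxa).

    Refuses to transform twice: the returned matrix carries
    ``transform="sqrt"``.
    """
    if matrix.transform == "sqrt":
        raise SaprolensError("matrix is already square-root transformed")
    return CommunityMatrix(
        np.sqrt(matrix.data),
        sample_meta=matrix.sample_meta,
        units=matrix.units,
        transform="sqrt",
    )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with labelled items."""

    ids: list[str]
    values: np.ndarray
    metric: str
    #: pairs that were 0/0 under Bray-Curtis, defined as 0 and flagged
    degenerate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise SaprolensError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise SaprolensError("distance matrix not symmetric")
        if np.diag(self.values).any():
            raise SaprolensError("distance matrix diagonal not zero")
        if (self.values < 0).any():
            raise SaprolensError("negative distances")

    @property
    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (i < j) order."""
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _standardize(data: pd.DataFrame) -> pd.DataFrame:
    std = data.std(ddof=1)
    constant = list(std.index[std == 0])
    if constant:
        raise MatrixError(f"zero-variance variables: {constant}")
    return (data - data.mean()) / std


def distance_matrix(data: pd.DataFrame, metric: str) -> DistanceMatrix:
    """Pairwise distances between the rows of ``data``.

    ``"normalized-euclidean"`` standardises each column to zero mean and
    unit (sample) SD first. Bray-Curtis distance of two all-zero rows is
    undefined (0/0); it is set to 0 and the pair recorded in
    ``degenerate_pairs``.
    """
    if metric not in METRICS:
        raise SaprolensError(f"unknown metric {metric!r}; choose from {METRICS}")
    ids = [str(i) for i in data.index]
    degenerate: list[tuple[str, str]] = []
    if metric == "euclidean":
        d = pdist(data.to_numpy(float), metric="euclidean")
    elif metric == "normalized-euclidean":
        d = pdist(_standardize(data).to_numpy(float), metric="euclidean")
    else:
        x = data.to_numpy(float)
        if (x < 0).any():
            raise SaprolensError("Bray-Curtis requires non-negative data")
        with np.errstate(invalid="ignore"):
            d = pdist(x, metric="braycurtis")
        if np.isnan(d).any():
            n = len(ids)
            iu, ju = np.triu_indices(n, 1)
            for k in np.flatnonzero(np.isnan(d)):
                degenerate.append((ids[iu[k]], ids[ju[k]]))
            d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(ids, squareform(d), metric, degenerate)


@dataclass
class Dendrogram:
    """Agglomeration result: a scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise SaprolensError("dendrogram needs at least 2 items")
        heights = self.linkage[:, 2]
        if (np.diff(heights) < -1e-10).any():
            raise SaprolensError("merge heights decrease (linkage inversion)")

    @property
    def max_height(self) -> float:
        return float(self.linkage[-1, 2])

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return rec(tree, tree.dist) + ";"


def ward_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Ward minimum-variance agglomeration of a (Euclidean) distance matrix.

    Uses the Lance-Williams update on the supplied distances; merge
    heights are non-decreasing when the input is Euclidean-compatible.
    """
    if len(dist.ids) < 2:
        raise SaprolensError("need at least 2 items to cluster")
    z = hierarchy.linkage(dist.condensed, method="ward")
    return Dendrogram(z, list(dist.ids))


def cut_at_similarity(dendro: Dendrogram, similarity_pct: float) -> pd.Series:
    """Partition at a similarity level.

    Similarity is defined against the final merge height ``h_max`` as
    ``100 * (1 - h / h_max)``; the tree is cut at the height
    corresponding to ``similarity_pct``. 0% yields one group, 100%
    singletons. Returns a Series mapping label -> integer group id.
    """
    if not (0 <= similarity_pct <= 100):
        raise SaprolensError("similarity_pct must be in [0, 100]")
    h_cut = (1.0 - similarity_pct / 100.0) * dendro.max_height
    flat = hierarchy.fcluster(dendro.linkage, t=h_cut, criterion="distance")
    return pd.Series(flat, index=dendro.labels, name="group")


def spearman_screen(
    index_table: pd.DataFrame, env_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlation of every (index, variable) pair.

    Rows must be aligned samples (n >= 4). Returns (rho, two-sided p)
    DataFrames indexed by index-table columns. Pairs involving a
    constant column are undefined and returned as NaN.
    """
    if not index_table.index.equals(env_table.index):
        raise MatrixError("index and environment tables are not sample-aligned")
    if len(index_table) < 4:
        raise SaprolensError("need at least 4 samples for a correlation screen")
    rho = pd.DataFrame(index=index_table.columns, columns=env_table.columns, dtype=float)
    pval = rho.copy()
    for a in index_table.columns:
        x = index_table[a].to_numpy(float)
        for b in env_table.columns:
            y = env_table[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho.loc[a, b] = np.nan
                pval.loc[a, b] = np.nan
                continue
            r, p = spearmanr(x, y)
            rho.loc[a, b] = r
            pval.loc[a, b] = p
    return rho, pval


@dataclass(frozen=True)
class MatrixCorrelationResult:
    """RELATE output: observed rho, permutation count, p, null summary."""

    rho: float
    n_permutations: int
    p_value: float
    permuted_rho_mean: float
    permuted_rho_max: float


def _spearman_condensed(x_ranked: np.ndarray, y: np.ndarray) -> float:
    yr = rankdata(y)
    return float(np.corrcoef(x_ranked, yr)[0, 1])


def relate(
    d_bio: DistanceMatrix,
    d_env: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MatrixCorrelationResult:
    """Mantel-type rank correlation between two dissimilarity matrices.

    rho is the Spearman correlation of the condensed (upper-triangle)
    entries. The null distribution relabels the samples of the second
    matrix (joint row/column permutation); the one-sided p-value is
    ``(1 + #{perm rho >= observed}) / (n_perm + 1)``.
    """
    if d_bio.ids != d_env.ids:
        raise MatrixError("distance matrices have different sample labels")
    if n_perm < 99:
        raise SaprolensError("use at least 99 permutations")
    n = len(d_bio.ids)
    x = rankdata(d_bio.condensed)
    x = (x - x.mean()) / x.std()
    obs = float(np.mean(x * _norm_ranks(d_env.condensed)))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    iu, ju = np.triu_indices(n, 1)
    permuted = d_env.values[perms[:, iu], perms[:, ju]]  # (n_perm, n_pairs)
    pr = rankdata(permuted, axis=1)
    pr = (pr - pr.mean(axis=1, keepdims=True)) / pr.std(axis=1, keepdims=True)
    null = pr @ x / x.size
    # tolerance so permutations tied with the observed statistic count
    p = (1.0 + np.sum(null >= obs - 1e-12)) / (n_perm + 1.0)
    return MatrixCorrelationResult(
        rho=obs,
        n_permutations=n_perm,
        p_value=float(p),
        permuted_rho_mean=float(null.mean()),
        permuted_rho_max=float(null.max()),
    )


def _norm_ranks(v: np.ndarray) -> np.ndarray:
    r = rankdata(v)
    return (r - r.mean()) / r.std()


@dataclass
class BioenvResult:
    """Ranked subset search results.

    ``table`` has one row per variable subset (columns ``k``,
    ``variables``, ``rho``) sorted by rho descending.
    """

    table: pd.DataFrame
    k_max: int
    bio_metric: str
    env_metric: str

    @property
    def best_subset(self) -> tuple[str, ...]:
        return tuple(self.table.iloc[0]["variables"])

    @property
    def best_rho(self) -> float:
        return float(self.table.iloc[0]["rho"])


MAX_SUBSETS = 1_000_000


def bioenv(
    bio: CommunityMatrix | DistanceMatrix,
    env: pd.DataFrame,
    k_max: int | None = None,
    bio_metric: str = "bray-curtis",
    seed: int | None = None,
) -> BioenvResult:
    """Best-subset biota-environment matching.

    The biotic dissimilarity is fixed (Bray-Curtis on square-root
    abundances by default when a community matrix is given; a
    pre-computed :class:`DistanceMatrix` is used as-is). For every
    subset of environmental variables up to size ``k_max``, the
    normalised-Euclidean environment dissimilarity is rank-correlated
    (Spearman) against the biotic matrix; subsets are returned ranked.
    """
    if isinstance(bio, CommunityMatrix):
        mat = bio if bio.transform == "sqrt" else sqrt_transform(bio)
        d_bio = distance_matrix(mat.data, bio_metric)
    else:
        d_bio = bio
    if list(map(str, env.index)) != d_bio.ids:
        raise MatrixError("environment samples do not match the biotic matrix")
    variables = list(env.columns)
    if k_max is None:
        k_max = len(variables)
    if not (1 <= k_max <= len(variables)):
        raise SaprolensError("k_max must be in [1, n_variables]")
    from math import comb

    n_subsets = sum(comb(len(variables), k) for k in range(1, k_max + 1))
    if n_subsets > MAX_SUBSETS:
        raise SaprolensError(
            f"{n_subsets} subsets exceed the {MAX_SUBSETS} guard; lower k_max"
        )
    z = _standardize(env).to_numpy(float)
    x = _norm_ranks(d_bio.condensed)
    rows = []
    for k in range(1, k_max + 1):
        for subset in itertools.combinations(range(len(variables)), k):
            d_env = pdist(z[:, subset], metric="euclidean")
            rho = float(np.mean(x * _norm_ranks(d_env)))
            rows.append(
                {"k": k, "variables": tuple(variables[i] for i in subset), "rho": rho}
            )
    table = (
        pd.DataFrame(rows)
        .sort_values("rho", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return BioenvResult(table, k_max, d_bio.metric, "normalized-euclidean")
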