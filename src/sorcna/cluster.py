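"""Size-weighted k-means over signed SOR profiles.

Each SOR segment is one feature weighted by its genomic length in bp, so a
40 Mb arm-level event influences the clustering far more than a 100 kb
focal one.  The objective minimised is

    sum_i sum_j  w_j * (x_ij - c_{a(i), j})^2

with per-feature weights w_j; centroids are plain means of member rows.
Sex chromosomes are excluded before clustering so that mixed-sex cohorts do
not cluster by sex.  After fitting, cluster labels are canonicalised by the
size-weighted mean signed burden of their centroids: cluster 1 is the most
loss-dominated, cluster k the most gain-dominated, making cluster
identities comparable across runs and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sor import SorSegment
from .stats import fisher_exact_2x2

__all__ = [
    "ClusterModel",
    "CrosstabResult",
    "exclude_sex_chromosomes",
    "weighted_kmeans",
    "cluster_crosstab",
]

_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def exclude_sex_chromosomes(segments: Sequence[SorSegment]) -> list[SorSegment]:
    """Drop segments on chrX/chrY, preserving order."""
    return [s for s in segments if s.chromosome not in _SEX_CHROMS]


@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series  # case_id -> cluster label in 1..k
    centroids: np.ndarray  # k x n_features, rows ordered by cluster label
    weights: np.ndarray
    objective: float
    seed: int
    restarts: int
    n_iter: int
    feature_names: tuple = ()

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def centroid_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.centroids,
            index=pd.Index(range(1, self.k + 1), name="cluster"),
            columns=list(self.feature_names) or None,
        )


def _weighted_sqdist(X: np.ndarray, centers: np.ndarray, w: np.ndarray) -> np.ndarray:
    # (n, k) matrix of weighted squared distances
    diff = X[:, None, :] - centers[None, :, :]
    return np.einsum("nkj,j->nk", diff * diff, w)


def _kmeanspp(X: np.ndarray, w: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = _weighted_sqdist(X, centers[:1], w)[:, 0]
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[c] = X[rng.integers(n)]
        else:
            centers[c] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, _weighted_sqdist(X, centers[c:c + 1], w)[:, 0])
    return centers


def _lloyd(X: np.ndarray, w: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int) -> tuple[np.ndarray, np.ndarray, float, int]:
    n = X.shape[0]
    centers = _kmeanspp(X, w, k, rng)
    assign = np.full(n, -1)
    prev_obj = np.inf
    for it in range(1, max_iter + 1):
        D = _weighted_sqdist(X, centers, w)
        new_assign = D.argmin(axis=1)
        # repair empty clusters: reseed to the point farthest from its centroid
        for _ in range(k):
            counts = np.bincount(new_assign, minlength=k)
            empty = np.flatnonzero(counts == 0)
            if empty.size == 0:
                break
            current = D[np.arange(n), new_assign]
            far = int(np.argmax(current))
            centers[empty[0]] = X[far]
            D = _weighted_sqdist(X, centers, w)
            new_assign = D.argmin(axis=1)
        obj_assign = float(D[np.arange(n), new_assign].sum())
        assert obj_assign <= prev_obj + 1e-9 * (1 + abs(prev_obj)), \
            "k-means objective increased during assignment"
        for c in range(k):
            centers[c] = X[new_assign == c].mean(axis=0)
        D = _weighted_sqdist(X, centers, w)
        obj = float(D[np.arange(n), new_assign].sum())
        assert obj <= obj_assign + 1e-9 * (1 + abs(obj_assign)), \
            "k-means objective increased during update"
        if np.array_equal(new_assign, assign):
            return assign, centers, obj, it
        assign, prev_obj = new_assign, obj
    return assign, centers, prev_obj, max_iter


def weighted_kmeans(matrix: Union[pd.DataFrame, np.ndarray], weights, k: int,
                    seed: int = 1, restarts: int = 100,
                    max_iter: int = 300) -> ClusterModel:
    """Feature-weighted k-means (Lloyd, k-means++ seeding, best of restarts).

    Deterministic given ``seed``.  ``weights`` are strictly positive
    per-feature weights (SOR segment sizes in bp); scaling all weights by a
    constant leaves the assignments unchanged.
    """
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        index = matrix.index
        feature_names = tuple(map(str, matrix.columns))
    else:
        X = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(X.shape[0])
        feature_names = ()
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size != X.shape[1]:
        raise ValueError("weights must be one value per feature")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k < 1 or k > n_distinct:
        raise ValueError(f"k must be in [1, {n_distinct}] (distinct rows), got {k}")

    master = np.random.default_rng(seed)
    run_seeds = master.integers(0, 2**31 - 1, size=restarts)
    best = None
    for run_seed in run_seeds:
        rng = np.random.default_rng(int(run_seed))
        assign, centers, obj, it = _lloyd(X, w, k, rng, max_iter)
        if best is None or obj < best[2] - 1e-12:
            best = (assign, centers, obj, it)
    assign, centers, obj, n_iter = best

    # canonical ordering: cluster 1 most loss-dominated, cluster k most gain-
    # dominated by size-weighted mean signed centroid burden
    scores = centers @ w
    order = np.argsort(scores, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[assign]
    centers = centers[order]

    return ClusterModel(
        k=k,
        assignments=pd.Series(labels, index=index, name="cluster"),
        centroids=centers,
        weights=w,
        objective=obj,
        seed=seed,
        restarts=restarts,
        n_iter=n_iter,
        feature_names=feature_names,
    )


@dataclass
class CrosstabResult:
    table: pd.DataFrame  # labels x clusters
    test: str
    p_value: Optional[float]


def cluster_crosstab(model: ClusterModel,
                     grouping: Union[pd.Series, Mapping]) -> CrosstabResult:
    """Contingency table of clinical label vs cluster.

    2x2 tables get a Fisher exact p-value, larger tables a chi-square test;
    single-row or single-column tables carry no test (p is None).
    """
    grouping = pd.Series(grouping)
    missing = model.assignments.index.difference(grouping.index)
    if len(missing) > 0:
        raise ValueError(f"missing label(s) for case(s): {list(missing)}")
    grouping = grouping.loc[model.assignments.index]
    table = pd.crosstab(grouping, model.assignments)
    table.index.name = grouping.name or "label"
    if table.shape == (2, 2):
        return CrosstabResult(table, "fisher", fisher_exact_2x2(table.to_numpy()).p_value)
    if min(table.shape) < 2:
        return CrosstabResult(table, "none", None)
    chi2 = sps.chi2_contingency(table.to_numpy())
    return CrosstabResult(table, "chi2", float(chi2.pvalue))
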