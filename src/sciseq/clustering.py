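"""Expression-trajectory clustering and sample-level QC clustering.

Genes whose floored stage means change more than 2-fold between at least two
stages are standardized to zero mean / unit variance across stages and
grouped into k fuzzy c-means clusters (k = 9 mirrors the nine trajectory
groups the injury time course resolves into).  For sample QC, the top-variance
genes feed complete-linkage hierarchical clustering on the 1 − Pearson
distance, plus a replicate correlation matrix.

The fuzzy c-means implementation is the classic Bezdek alternating scheme:

    u_ij = 1 / Σ_l (d_ij / d_lj)^(2/(m-1)),   c_i = Σ_j u_ij^m x_j / Σ_j u_ij^m

with objective J = Σ_ij u_ij^m d_ij², guaranteed non-increasing per
iteration.  Centers are initialized by k-means++-style seeding so that a
fixed seed fixes the result.  The fuzzifier default m = 1.25 is a common
choice for standardized expression trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionStudy, ValidationError


def select_varying_genes(
    study: ExpressionStudy, min_fc: float = 2.0, floor: float = 0.1
) -> list[str]:
    """Genes whose floored stage means change more than ``min_fc``-fold
    between at least two stages (max mean / min mean > min_fc)."""
    means = study.stage_means(floor=floor)
    ratio = means.max(axis=1) / means.min(axis=1)
    return list(means.index[ratio > min_fc])


def standardize_profiles(stage_means: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene's stage profile (population sd across stages)."""
    x = stage_means.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # ddof=0 by convention
    if (sd == 0).any():
        bad = stage_means.index[(sd == 0).ravel()][:5]
        raise ValidationError(
            f"constant profile(s) cannot be standardized: {list(bad)}"
        )
    return pd.DataFrame((x - mu) / sd, index=stage_means.index,
                        columns=stage_means.columns)


@dataclass
class FuzzyClustering:
    centers: pd.DataFrame      # k × n_stages
    memberships: pd.DataFrame  # genes × k, rows sum to 1
    m: float
    objective_path: list[float]
    n_iter: int

    @property
    def k(self) -> int:
        return len(self.centers)

    def hard_assignments(self) -> pd.Series:
        return self.memberships.idxmax(axis=1)


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    centers = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            ((x[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
        centers.append(x[rng.choice(n, p=probs)])
    return np.asarray(centers)


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    k: int = 9,
    m: float = 1.25,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> FuzzyClustering:
    """Fuzzy c-means over standardized trajectory profiles."""
    if m <= 1:
        raise ValidationError("fuzzifier m must exceed 1")
    x = profiles.to_numpy(dtype=float)
    n = len(x)
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of genes ({n})")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(x, k, rng)
    expo = 2.0 / (m - 1.0)
    objective_path: list[float] = []
    u = None
    for it in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)  # n × k
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo / 2.0)
            u = inv / inv.sum(axis=1, keepdims=True)
        if zero.any():  # gene exactly on a center: full membership there
            rows = zero.any(axis=1)
            u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        obj = float((u**m * d2).sum())
        objective_path.append(obj)
        um = u**m
        centers_new = (um.T @ x) / um.sum(axis=0)[:, None]
        if it > 0 and objective_path[-2] - obj < tol:
            centers = centers_new
            break
        centers = centers_new
    cluster_ids = [f"c{i+1}" for i in range(k)]
    return FuzzyClustering(
        centers=pd.DataFrame(centers, index=cluster_ids, columns=profiles.columns),
        memberships=pd.DataFrame(u, index=profiles.index, columns=cluster_ids),
        m=m,
        objective_path=objective_path,
        n_iter=len(objective_path),
    )


def replicate_correlation(study: ExpressionStudy) -> pd.DataFrame:
    """Sample × sample Pearson correlation of expression profiles."""
    if study.values.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    sds = study.values.std(axis=0, ddof=0)
    corr = study.values.corr(method="pearson")
    for s in sds.index[sds == 0]:
        corr.loc[s, :] = np.nan
        corr.loc[:, s] = np.nan
        corr.loc[s, s] = 1.0
    return corr


@dataclass
class SampleDendrogram:
    linkage: np.ndarray
    labels: list[str]
    distance: pd.DataFrame

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def newick(self) -> str:
        """Nested-parenthesis text of the merge tree with heights."""
        tree = hierarchy.to_tree(self.linkage)

        def _walk(node):
            if node.is_leaf():
                return self.labels[node.id]
            return f"({_walk(node.left)},{_walk(node.right)}):{node.dist:.6g}"

        return _walk(tree) + ";"


def hierarchical_samples(
    study: ExpressionStudy, top_n: int = 3000
) -> SampleDendrogram:
    """Complete-linkage clustering of samples on 1 − Pearson distance.

    The ``top_n`` genes with highest variance across samples are used.
    Sample columns are taken in sorted-id order so the result is invariant
    to input sample ordering.
    """
    if study.values.shape[1] < 3:
        raise ValidationError("need at least 3 samples for a dendrogram")
    variances = study.values.var(axis=1, ddof=0)
    zero_sd = study.values.std(axis=0, ddof=0) == 0
    if zero_sd.any():
        raise ValidationError(
            f"constant sample(s): {list(study.values.columns[zero_sd])}"
        )
    top = variances.sort_values(ascending=False, kind="mergesort").index[:top_n]
    labels = sorted(study.values.columns)
    sub = study.values.loc[top, labels]
    dist = 1.0 - sub.corr(method="pearson")
    condensed = squareform(np.clip(dist.to_numpy(), 0.0, None), checks=False)
    z = hierarchy.linkage(condensed, method="complete")
    return SampleDendrogram(linkage=z, labels=labels, distance=dist)
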