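"""Environmental clustering of deployments and rank-based group comparisons.

Deployments are clustered on their environmental conditions by HCPC:
KMO-screened variables → PCA on the correlation matrix → Ward dendrogram on
the retained component scores → k-means consolidation initialized at the
dendrogram-cut centroids.  Acoustic detections (dp10m) are then compared
across deployments / months / clusters with Kruskal–Wallis (tie-corrected)
and Nemenyi all-pairs post-hoc tests; the exploratory normality and
variance-homogeneity checks motivate the rank-based route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ValidationError


# ---------------------------------------------------------------------------
# exploratory distribution checks


def anderson_darling_normal(x: np.ndarray) -> tuple[float, float]:
    """Anderson–Darling normality test with the Stephens small-sample p-value.

    Returns (A², p).  Mean and variance are estimated from the sample; the
    p-value uses the modified statistic A*² = A²(1 + 0.75/n + 2.25/n²).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 8:
        raise ValidationError("need at least 8 values")
    s = x.std(ddof=1)
    if s == 0:
        raise ValidationError("constant sample: normality test undefined")
    z = (x - x.mean()) / s
    cdf = stats.norm.cdf(z)
    cdf = np.clip(cdf, 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (np.log(cdf) + np.log(1 - cdf[::-1]))) / n
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2s >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s**2)
    elif a2s > 0.34:
        p = math.exp(0.9177 - 4.279 * a2s - 1.38 * a2s**2)
    elif a2s > 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2s - 59.938 * a2s**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2s - 223.73 * a2s**2)
    return float(a2), float(min(max(p, 0.0), 1.0))


def check_distributions(values: np.ndarray, groups: np.ndarray) -> dict:
    """Normality (Anderson–Darling, pooled) and Levene (median-centered)
    homogeneity of variances across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) < 8:
        raise ValidationError("need at least 8 values")
    a2, p_norm = anderson_darling_normal(values)
    arrays = [values[groups == g] for g in np.unique(groups)]
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValidationError("constant input: Levene test degenerate")
    w, p_lev = stats.levene(*arrays, center="median")
    return {"ad_stat": a2, "ad_p": p_norm, "levene_stat": float(w), "levene_p": float(p_lev)}


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Nemenyi


@dataclass
class GroupTestResult:
    grouping: str
    chi2: float
    df: int
    p: float
    nemenyi_p: pd.DataFrame  # symmetric all-pairs p-value matrix
    method: str


def kruskal_nemenyi(
    values: np.ndarray,
    groups: np.ndarray,
    grouping_name: str = "group",
    method: str = "chisq",
) -> GroupTestResult:
    """Tie-corrected Kruskal–Wallis with Nemenyi all-pairs comparisons.

    ``method='chisq'`` uses the chi-square approximation of the Nemenyi
    statistic (with the same tie correction as the omnibus test);
    ``method='tukey'`` uses the Studentized-range formulation.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    for g in levels:
        if np.sum(groups == g) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 values")
    n = len(values)
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_c = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie_c == 0:
        raise ValidationError("all values identical")
    rbar = {g: ranks[groups == g].mean() for g in levels}
    ng = {g: int(np.sum(groups == g)) for g in levels}
    h = (12.0 / (n * (n + 1)) * sum(ng[g] * rbar[g] ** 2 for g in levels) - 3 * (n + 1)) / tie_c
    df = len(levels) - 1
    p = float(stats.chi2.sf(h, df))

    pmat = pd.DataFrame(np.ones((len(levels), len(levels))), index=levels, columns=levels)
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            diff = abs(rbar[a] - rbar[b])
            if method == "chisq":
                stat = diff**2 / (n * (n + 1) / 12.0 * (1.0 / ng[a] + 1.0 / ng[b])) / tie_c
                pv = float(stats.chi2.sf(stat, df))
            elif method == "tukey":
                se = math.sqrt(n * (n + 1) / 24.0 * (1.0 / ng[a] + 1.0 / ng[b]))
                q = diff / se
                pv = float(stats.studentized_range.sf(q, len(levels), np.inf))
            else:
                raise ValidationError(f"unknown Nemenyi method {method!r}")
            pmat.loc[a, b] = pmat.loc[b, a] = pv
    return GroupTestResult(grouping_name, float(h), df, p, pmat, method)


# ---------------------------------------------------------------------------
# HCPC


@dataclass
class PCAResult:
    variables: list[str]
    loadings: pd.DataFrame
    scores: pd.DataFrame
    proportion: np.ndarray
    cumulative: np.ndarray
    n_retained: int


@dataclass
class ClusterAssignment:
    labels: pd.Series  # deployment_id -> cluster id (1-based)
    merge_heights: np.ndarray
    k: int
    consolidation_iterations: int


def _choose_k_from_dendrogram(heights: np.ndarray, k_range=(2, 6)) -> int:
    """Largest relative gap between successive merge heights within k ∈ [2,6]."""
    # cutting between the last k and k-1 merges leaves k clusters
    h = np.asarray(heights, dtype=float)
    best_k, best_gap = k_range[0], -np.inf
    n = len(h) + 1
    for k in range(k_range[0], min(k_range[1], n - 1) + 1):
        upper = h[-(k - 1)] if k > 1 else np.inf
        lower = h[-k]
        gap = (upper - lower) / max(lower, 1e-12)
        if gap > best_gap:
            best_k, best_gap = k, gap
    return best_k


def hcpc(
    env_table: pd.DataFrame,
    var_threshold: float = 0.70,
    k: int | None = None,
    k_range=(2, 6),
    seed: int = 0,
) -> tuple[PCAResult, ClusterAssignment]:
    """Hierarchical clustering on principal components.

    ``env_table`` is a deployments × variables frame (index = deployment id),
    already KMO-screened.  Columns are standardized (correlation PCA), the
    smallest prefix of components reaching ``var_threshold`` cumulative
    variance is retained, a Ward dendrogram built on the scores, ``k``
    chosen from the largest relative height gap (unless given), and the cut
    consolidated by k-means started at the cluster centroids.
    """
    if env_table.isna().any().any():
        raise ValidationError("env table contains missing values")
    X = env_table.to_numpy(dtype=float)
    n, m = X.shape
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError("constant environmental column")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=min(n, m))
    scores = pca.fit_transform(Z)
    prop = pca.explained_variance_ratio_
    cum = np.cumsum(prop)
    n_ret = int(np.searchsorted(cum, var_threshold) + 1)
    n_ret = min(n_ret, scores.shape[1])
    pca_res = PCAResult(
        variables=list(env_table.columns),
        loadings=pd.DataFrame(
            pca.components_.T,
            index=env_table.columns,
            columns=[f"PC{i+1}" for i in range(pca.n_components_)],
        ),
        scores=pd.DataFrame(
            scores, index=env_table.index, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
        ),
        proportion=prop,
        cumulative=cum,
        n_retained=n_ret,
    )
    S = scores[:, :n_ret]
    link = linkage(S, method="ward")
    k_eff = k if k is not None else _choose_k_from_dendrogram(link[:, 2], k_range)
    if k_eff > n:
        raise ValidationError(f"k={k_eff} exceeds {n} deployments")
    cut = fcluster(link, t=k_eff, criterion="maxclust")
    centroids = np.vstack([S[cut == c].mean(axis=0) for c in range(1, k_eff + 1)])
    km = KMeans(n_clusters=k_eff, init=centroids, n_init=1, random_state=seed)
    labels = km.fit_predict(S) + 1
    assignment = ClusterAssignment(
        labels=pd.Series(labels, index=env_table.index, name="cluster"),
        merge_heights=link[:, 2],
        k=k_eff,
        consolidation_iterations=int(km.n_iter_),
    )
    return pca_res, assignment


def deployment_env_table(records_frame: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Per-deployment environmental summary (mean over the monitored hours)."""
    return records_frame.groupby("deployment_id")[variables].mean()
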