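"""Masked Spearman correlation between cells, hierarchical clustering and
bootstrap-based outlier exclusion.

Zero expression in single-cell 5'-tag data mostly reflects dropout, so the
correlation between two cells is computed on "complete pairs": features
where both cells are nonzero. The coefficient matrix is then clustered with
complete linkage on Euclidean distances between its rows, and samples whose
cluster membership is unstable under feature bootstrap are flagged as
outliers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats


@dataclass
class CorrelationMatrix:
    corr: pd.DataFrame  # sample x sample Spearman coefficients (NaN = undefined)
    n_pairs: pd.DataFrame  # complete-observation counts per pair
    pvalues: pd.DataFrame  # two-sided t-approximation p-values
    bonferroni_significant: pd.DataFrame  # p * n_tests < alpha
    n_tests: int
    alpha: float = 0.05


def _masked_spearman_pair(x: np.ndarray, y: np.ndarray, min_pairs: int):
    mask = (x > 0) & (y > 0)
    n = int(mask.sum())
    if n < min_pairs:
        return np.nan, np.nan, n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> NaN, handled below
        rho, p = scipy.stats.spearmanr(x[mask], y[mask])
    return float(rho), float(p), n


def masked_spearman(values: pd.DataFrame, min_pairs: int = 30, alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Spearman on complete (both-nonzero) observations.

    Pairs with fewer than ``min_pairs`` complete observations are undefined
    (NaN). P-values use the t-approximation; the Bonferroni family is the
    number of distinct sample pairs tested in this run.
    """
    samples = list(values.columns)
    k = len(samples)
    if k < 2:
        raise ValueError("need at least 2 samples")
    mat = values.to_numpy(dtype=float)
    corr = np.eye(k)
    pvals = np.zeros((k, k))
    npairs = np.zeros((k, k), dtype=int)
    np.fill_diagonal(npairs, int((mat > 0).sum(axis=0).min()) if k else 0)
    for i in range(k):
        npairs[i, i] = int((mat[:, i] > 0).sum())
        for j in range(i + 1, k):
            rho, p, n = _masked_spearman_pair(mat[:, i], mat[:, j], min_pairs)
            corr[i, j] = corr[j, i] = rho
            pvals[i, j] = pvals[j, i] = p
            npairs[i, j] = npairs[j, i] = n
    n_tests = k * (k - 1) // 2
    signif = pvals * n_tests < alpha
    np.fill_diagonal(signif, True)
    idx = pd.Index(samples)
    return CorrelationMatrix(
        pd.DataFrame(corr, idx, idx),
        pd.DataFrame(npairs, idx, idx),
        pd.DataFrame(pvals, idx, idx),
        pd.DataFrame(signif, idx, idx),
        n_tests,
        alpha,
    )


def hcluster(corr: CorrelationMatrix | pd.DataFrame) -> tuple[np.ndarray, list[str], str]:
    """Complete-linkage clustering of coefficient-matrix rows.

    Rows of the (sample x sample) coefficient matrix are the feature
    vectors; distances are Euclidean. Undefined coefficients are imputed as
    0 with a warning. Returns (scipy linkage matrix, leaf order, newick).
    """
    df = corr.corr if isinstance(corr, CorrelationMatrix) else corr
    samples = list(df.columns)
    if len(samples) == 1:
        return np.zeros((0, 4)), samples, f"{samples[0]};"
    mat = df.to_numpy(dtype=float)
    if np.isnan(mat).any():
        warnings.warn("undefined correlations imputed as 0 for clustering")
        mat = np.nan_to_num(mat, nan=0.0)
    Z = sch.linkage(mat, method="complete", metric="euclidean")
    order = [samples[i] for i in sch.leaves_list(Z)]
    newick = _to_newick(sch.to_tree(Z), samples)
    return Z, order, newick


def _to_newick(node, names: list[str]) -> str:
    def rec(n, parent_dist: float) -> str:
        length = max(parent_dist - n.dist, 0.0)
        if n.is_leaf():
            return f"{names[n.id]}:{length:g}"
        return f"({rec(n.left, n.dist)},{rec(n.right, n.dist)}):{length:g}"

    return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)});"


def bootstrap_outliers(
    values: pd.DataFrame,
    stages: pd.Series,
    B: int = 100,
    consensus: float = 0.7,
    min_pairs: int = 30,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Flag samples with unstable stage-cluster membership under bootstrap.

    For each of B bootstrap resamples of features (rows, with replacement)
    the masked-Spearman matrix is re-clustered and cut at k = number of
    stages; a sample "joins" its stage when it lands in the cluster holding
    the majority of the other samples of its own stage. Samples joining in
    fewer than ``consensus`` of resamples are outliers. Single-sample stages
    are never flagged (no majority exists) and produce a warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = rng or np.random.default_rng()
    samples = list(values.columns)
    stages = stages.reindex(samples)
    k = stages.nunique()
    singleton_stages = {s for s, n in stages.value_counts().items() if n == 1}
    if singleton_stages:
        warnings.warn(f"stage(s) with a single sample never flagged: {sorted(singleton_stages)}")

    joined = np.zeros(len(samples))
    n_feat = values.shape[0]
    for _ in range(B):
        idx = rng.integers(0, n_feat, size=n_feat)
        boot = values.iloc[idx]
        cm = masked_spearman(boot, min_pairs=min_pairs)
        mat = np.nan_to_num(cm.corr.to_numpy(), nan=0.0)
        Z = sch.linkage(mat, method="complete", metric="euclidean")
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
        for si, s in enumerate(samples):
            peers = [j for j, p in enumerate(samples) if p != s and stages.iloc[j] == stages.iloc[si]]
            if not peers:
                joined[si] += 1
                continue
            peer_labels = labels[peers]
            majority = np.bincount(peer_labels).argmax()
            if labels[si] == majority:
                joined[si] += 1
    support = joined / B
    flags = (support < consensus) & ~stages.isin(singleton_stages).to_numpy()
    return pd.DataFrame(
        {"stage": stages.to_numpy(), "support": support, "outlier": flags}, index=samples
    )
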