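"""Spike-in-depth resampling Wilcoxon test with permutation FDR, plus the
cell-division correction that separates active degradation from dilution.

Counts are binomially thinned to the shallowest spike-in depth (so every
sample has the same expected spike-relative depth), a centered Wilcoxon
rank-sum statistic is averaged over R resamples, and q-values come from a
SAM-style permutation FDR (median permuted exceedance count over observed
exceedance count, monotonized).

Down-regulation ("actively reduced") is called only after multiplying the
later stage by the number of intervening cell divisions D (4 for
oocyte -> 4-cell, 2 for 4- -> 8-cell), which cancels the passive per-cell
content reduction from cleavage. Up-regulation is called without correction.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .normalize import ExpressionMatrix

DEFAULT_DIVISIONS = {("oocyte", "4cell"): 4, ("4cell", "8cell"): 2}


@dataclass
class DEParams:
    resamples: int = 20  # R
    permutations: int = 1000  # P
    divisions: int = 1  # D, cell divisions between the two stages
    q_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resamples < 1:
            raise ValueError("resamples must be >= 1")
        if self.permutations < 10:
            raise ValueError("permutations must be >= 10")
        if self.divisions < 1 or int(self.divisions) != self.divisions:
            raise ValueError("divisions must be a positive integer")


def resample_to_common_depth(
    counts: np.ndarray, spike_depths: np.ndarray, resamples: int, rng: np.random.Generator
) -> np.ndarray:
    """Binomially thin each sample's counts to the minimum spike depth.

    Returns an (R, features, samples) array; sample s is thinned with
    probability min(depth)/depth_s, independently per resample.
    """
    counts = np.asarray(counts)
    depths = np.asarray(spike_depths, dtype=float)
    if np.any(depths <= 0):
        raise ValueError("spike depths must be positive")
    p = depths.min() / depths
    out = np.empty((resamples,) + counts.shape, dtype=np.int64)
    for r in range(resamples):
        out[r] = rng.binomial(counts, p[None, :])
    return out


def _midranks(thinned: np.ndarray) -> np.ndarray:
    """Mid-ranks along the sample axis for every resample and feature."""
    return scipy.stats.rankdata(thinned, axis=-1, method="average")


def rank_statistic(thinned: np.ndarray, group2: np.ndarray) -> np.ndarray:
    """Centered Wilcoxon rank-sum statistic averaged over resamples.

    Sum of group-2 mid-ranks minus its null expectation n2*(n+1)/2;
    positive values mean higher expression in group 2.
    """
    group2 = np.asarray(group2, dtype=bool)
    n = group2.size
    n2 = int(group2.sum())
    if n2 < 2 or n - n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    # the statistic is linear in the ranks, so the resample average of the
    # group sum equals the group sum of the resample-averaged ranks
    mean_ranks = _midranks(thinned).mean(axis=0)
    null_mean = n2 * (n + 1) / 2.0
    return mean_ranks[..., group2].sum(axis=-1) - null_mean


def _permutation_group2_sets(
    n: int, n2: int, permutations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Group-2 index sets: exhaustive when feasible, else sampled."""
    total = math.comb(n, n2)
    if total <= permutations:
        return [np.array(c) for c in itertools.combinations(range(n), n2)]
    return [rng.permutation(n)[:n2] for _ in range(permutations)]


def permutation_fdr(
    statistics: np.ndarray,
    thinned: np.ndarray,
    group2: np.ndarray,
    permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """SAM-style permutation q-values.

    At threshold t = |s_i|: FDR = median over permutations of the count of
    permuted |statistics| >= t, divided by the observed count >= t, then
    monotonized to be non-increasing in |s| and clipped to [0, 1].
    """
    group2 = np.asarray(group2, dtype=bool)
    n = group2.size
    n2 = int(group2.sum())
    mean_ranks = _midranks(thinned).mean(axis=0)  # (features, samples)
    null_mean = n2 * (n + 1) / 2.0
    perm_sets = _permutation_group2_sets(n, n2, permutations, rng)

    indicator = np.zeros((n, len(perm_sets)))
    for pi, idx in enumerate(perm_sets):
        indicator[idx, pi] = 1.0
    perm_stats = mean_ranks @ indicator - null_mean  # (features, permutations)

    abs_obs = np.abs(np.asarray(statistics, dtype=float))
    perm_counts = np.empty((len(perm_sets), abs_obs.size))
    for pi in range(len(perm_sets)):
        row = np.sort(np.abs(perm_stats[:, pi]))
        # permuted |stats| >= |s_i| for every observed threshold at once
        perm_counts[pi] = row.size - np.searchsorted(row, abs_obs, side="left")
    med_perm = np.median(perm_counts, axis=0)

    sorted_abs = np.sort(abs_obs)
    obs_counts = abs_obs.size - np.searchsorted(sorted_abs, abs_obs, side="left")
    fdr = med_perm / obs_counts  # obs_counts >= 1 (each feature exceeds itself)

    # q_i = min FDR over rejection regions containing i, i.e. over all
    # thresholds at or below |s_i|; ascending running min makes q
    # non-increasing in |s|
    order = np.argsort(abs_obs, kind="stable")
    q = np.empty_like(fdr)
    running = np.inf
    for i in order:
        running = min(running, fdr[i])
        q[i] = running
    return np.clip(q, 0.0, 1.0)


def de_test(
    counts: pd.DataFrame,
    spike_depths: pd.Series,
    group2: np.ndarray,
    params: DEParams,
    scale_group2: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """One resampling rank test run; returns (statistics, q-values).

    ``scale_group2`` multiplies group-2 raw counts before thinning — the
    cell-division correction.
    """
    rng = np.random.default_rng(params.seed)
    mat = counts.to_numpy(dtype=np.int64).copy()
    if scale_group2 != 1:
        mat[:, np.asarray(group2, dtype=bool)] *= int(scale_group2)
    depths = spike_depths[counts.columns].to_numpy(dtype=float)
    thinned = resample_to_common_depth(mat, depths, params.resamples, rng)
    stats = rank_statistic(thinned, group2)
    q = permutation_fdr(stats, thinned, group2, params.permutations, rng)
    return stats, q


def call_de(
    matrix: ExpressionMatrix, transition: tuple[str, str], params: DEParams
) -> pd.DataFrame:
    """Call up- and down-regulated TFEs across a stage transition.

    Runs the test twice: uncorrected for "up" calls (sign toward the later
    stage), and with later-stage counts multiplied by D = params.divisions
    for "down" calls (actively reduced beyond dilution). Both runs share the
    seed, so D = 1 reproduces the uncorrected run exactly.
    """
    early, late = transition
    stages = matrix.stages
    samples = [s for s in matrix.values.columns if stages[s] in transition]
    sub = matrix.subset(samples)
    group2 = np.array([stages[s] == late for s in samples])
    counts = sub.raw_counts()

    stat_u, q_u = de_test(counts, sub.spike_depths, group2, params, scale_group2=1)
    if params.divisions == 1:
        stat_c, q_c = stat_u, q_u
    else:
        stat_c, q_c = de_test(
            counts, sub.spike_depths, group2, params, scale_group2=params.divisions
        )

    up = (q_u < params.q_threshold) & (stat_u > 0)
    down = (q_c < params.q_threshold) & (stat_c < 0)
    conflict = up & down
    if conflict.any():
        bad = list(counts.index[conflict][:5])
        raise ValueError(f"TFE(s) called both up and down: {bad}")
    direction = np.where(up, "up", np.where(down, "down", "none"))
    return pd.DataFrame(
        {
            "tfe": counts.index,
            "statistic": stat_u,
            "q_value": q_u,
            "statistic_corrected": stat_c,
            "q_value_corrected": q_c,
            "direction": direction,
            "divisions": params.divisions,
        }
    ).set_index("tfe")
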