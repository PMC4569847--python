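"""Spike-in based absolute normalization and per-cell RNA-content estimation.

Because spike-in molecules are added at a fixed amount per well, expression
per 1,000 spike-in tags is proportional to molecules per cell, independent
of how much RNA the cell contained — the property that separates genuine
transcription from dilution by cleavage.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

SCALE = 1000.0  # normalized unit: tags per 1,000 spike-in tags


@dataclass
class ExpressionMatrix:
    """Spike-normalized TFE x sample expression with sample metadata."""

    values: pd.DataFrame  # TFE x sample, tags per 1,000 spike tags
    spike_depths: pd.Series  # sample -> spike-in tag count
    stages: pd.Series  # sample -> stage label

    def raw_counts(self) -> pd.DataFrame:
        """Invert the normalization back to integer tag counts."""
        counts = self.values.mul(self.spike_depths, axis=1) / SCALE
        return counts.round().astype(int)

    def subset(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples], self.spike_depths[samples], self.stages[samples]
        )


def spikein_normalize(
    counts: pd.DataFrame, spike_depths: pd.Series, stages: pd.Series
) -> ExpressionMatrix:
    """value(t, s) = count(t, s) / spike_depth(s) * 1,000."""
    zero = spike_depths[spike_depths <= 0]
    if len(zero):
        raise ValueError(f"zero spike-in depth for sample(s): {', '.join(zero.index)}")
    depths = spike_depths[counts.columns].astype(float)
    values = counts.div(depths, axis=1) * SCALE
    return ExpressionMatrix(values, spike_depths[counts.columns], stages[counts.columns])


def rna_content(
    samples: pd.DataFrame, stage_pair: tuple[str, str]
) -> pd.DataFrame:
    """Relative poly(A) RNA content per cell for two stages.

    ``samples`` needs columns sample_id, stage, genomic_tags, spike_tags.
    The per-sample ratio genomic/spike is divided by the mean ratio of the
    earlier stage, so the earlier-stage centered mean is 1.
    """
    early, late = stage_pair
    sub = samples[samples["stage"].isin(stage_pair)].copy()
    sub["ratio"] = sub["genomic_tags"] / sub["spike_tags"]
    early_ratios = sub.loc[sub["stage"] == early, "ratio"]
    if early_ratios.empty:
        raise ValueError(f"no samples in earlier stage {early!r}")
    sub["centered_ratio"] = sub["ratio"] / early_ratios.mean()
    return sub[["sample_id", "stage", "ratio", "centered_ratio"]].reset_index(drop=True)


def content_stage_test(earlier: Sequence[float], later: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two stages.

    Exact when both groups have <= 25 observations and no ties; normal
    approximation with tie correction otherwise. All values tied across both
    groups yields p = 1.
    """
    x = np.asarray(earlier, dtype=float)
    y = np.asarray(later, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both stages need at least one sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= 25 and y.size <= 25 and not has_ties) else "asymptotic"
    return float(
        scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )
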