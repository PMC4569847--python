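"""Two-tier sample exclusion: fixed prefilter, then cohort-adaptive cut-offs.

Prefilter drops wells with shallow sequencing depth (< 100k reads) or no
detected spike-in reads. After alignment, adaptive cut-offs at
mean - k*s.d. of log10 sequenced reads and of mapping rate (k = 2 by
default) plus a fixed minimum of 50 spike-in reads discard failed samples.
All comparisons are strict "<".
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class QCThresholds:
    min_raw_reads: int = 100_000
    min_spike_reads: int = 50
    k_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.min_raw_reads < 0 or self.min_spike_reads < 0 or self.k_sd < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class SampleQC:
    """Per-sample sequencing statistics plus exclusion flags."""

    sample: str
    raw_reads: int
    mapped_reads: int
    spike_reads: int
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def mapping_rate(self) -> float:
        return self.mapped_reads / self.raw_reads if self.raw_reads > 0 else 0.0

    @property
    def log10_raw(self) -> float:
        return math.log10(self.raw_reads) if self.raw_reads > 0 else float("-inf")


def prefilter_samples(
    samples: Sequence[SampleQC], thresholds: QCThresholds | None = None
) -> tuple[list[SampleQC], list[tuple[SampleQC, str]]]:
    """Fixed-threshold exclusion: depth < min_raw_reads or zero spike reads."""
    thr = thresholds or QCThresholds()
    kept, excluded = [], []
    for s in samples:
        if s.raw_reads < thr.min_raw_reads:
            s.flags["depth"] = True
            excluded.append((s, "depth"))
        elif s.spike_reads == 0:
            s.flags["no spike-ins"] = True
            excluded.append((s, "no spike-ins"))
        else:
            kept.append(s)
    return kept, excluded


def adaptive_exclusion(
    samples: Sequence[SampleQC], thresholds: QCThresholds | None = None
) -> tuple[list[SampleQC], list[tuple[SampleQC, str]], dict[str, float]]:
    """Cohort-adaptive exclusion after alignment.

    Cut-offs are mean - k*s.d. (sample s.d., n-1) of log10 sequenced reads
    and of mapping rates over the input cohort; a sample additionally fails
    below the fixed spike-read minimum. Returns (kept, excluded-with-reason,
    cohort statistics).
    """
    thr = thresholds or QCThresholds()
    if len(samples) < 2:
        raise ValueError("cohort too small for adaptive thresholds")
    log_reads = np.array([s.log10_raw for s in samples])
    rates = np.array([s.mapping_rate for s in samples])
    stats = {
        "mean_log10_reads": float(log_reads.mean()),
        "sd_log10_reads": float(log_reads.std(ddof=1)),
        "mean_mapping_rate": float(rates.mean()),
        "sd_mapping_rate": float(rates.std(ddof=1)),
    }
    stats["cutoff_log10_reads"] = stats["mean_log10_reads"] - thr.k_sd * stats["sd_log10_reads"]
    stats["cutoff_mapping_rate"] = stats["mean_mapping_rate"] - thr.k_sd * stats["sd_mapping_rate"]

    kept, excluded = [], []
    for s in samples:
        reason = None
        if s.log10_raw < stats["cutoff_log10_reads"]:
            reason = "shallow reads"
        elif s.mapping_rate < stats["cutoff_mapping_rate"]:
            reason = "low mapping rate"
        elif s.spike_reads < thr.min_spike_reads:
            reason = "shallow spike-ins"
        if reason is None:
            kept.append(s)
        else:
            s.flags[reason] = True
            excluded.append((s, reason))
    return kept, excluded, stats


def qc_from_tags(tags: Iterable, sheet: pd.DataFrame) -> list[SampleQC]:
    """Build SampleQC records from simulated/ingested aligned tags.

    With alignment-level input every record is mapped, so raw = mapped and
    the mapping rate is 1; real pipelines would fill raw read totals from
    sequencing metrics.
    """
    totals: dict[str, int] = {}
    spikes: dict[str, int] = {}
    for t in tags:
        totals[t.sample] = totals.get(t.sample, 0) + 1
        if t.spike:
            spikes[t.sample] = spikes.get(t.sample, 0) + 1
    return [
        SampleQC(s, totals.get(s, 0), totals.get(s, 0), spikes.get(s, 0))
        for s in sheet["sample_id"]
    ]


def qc_table(samples: Sequence[SampleQC]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample,
            "raw_reads": s.raw_reads,
            "mapped_reads": s.mapped_reads,
            "mapping_rate": s.mapping_rate,
            "spike_reads": s.spike_reads,
            "log10_raw_reads": s.log10_raw,
            "fail_reasons": ";".join(k for k, v in s.flags.items() if v),
        }
        for s in samples
    ]
    return pd.DataFrame(rows)
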