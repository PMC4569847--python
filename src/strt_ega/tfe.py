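"""Assembly of 5'-tag alignments into transcript far 5'-end (TFE) features.

A TFE is a strand-specific cluster of read 5' ends marking a transcript start
region. Tags are clustered per sample type by gap-bounded single linkage,
sample-type clusters overlapping on the same contig+strand are unioned into
one feature, and tags are then counted per sample against the merged set.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AlignedTag:
    """One mapped read reduced to its strand-aware 5'-end position."""

    contig: str
    pos: int  # 0-based 5'-end position
    strand: str
    sample: str
    spike: bool = False


@dataclass
class AssemblyParams:
    """Clustering parameters.

    min_tags: minimum tags supporting a cluster (clusters below are dropped).
    max_gap: maximum distance (bp) between a tag and its nearest cluster
             member for single-linkage chaining.
    """

    min_tags: int = 5
    max_gap: int = 60

    def __post_init__(self) -> None:
        if self.min_tags < 1:
            raise ValueError("min_tags must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass
class ProtoTFE:
    """A per-sample-type cluster of tag 5' ends before cross-type merging."""

    contig: str
    strand: str
    start: int
    end: int  # half-open
    n_tags: int
    sample_type: str


@dataclass
class TFE:
    """A merged transcript far 5'-end feature."""

    id: str
    contig: str
    strand: str
    start: int
    end: int
    sample_types: set[str] = field(default_factory=set)
    peak: Optional[int] = None
    counts: Counter = field(default_factory=Counter)  # sample -> tag count

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def cluster_tags(
    tags: Iterable[AlignedTag], params: AssemblyParams, sample_type: str
) -> list[ProtoTFE]:
    """Single-linkage cluster tag 5' positions on each (contig, strand).

    Two tags join the same cluster iff their positions differ by at most
    ``params.max_gap`` from the nearest member (equivalently, sorted adjacent
    gaps <= max_gap). Clusters supported by fewer than ``params.min_tags``
    tags are discarded. Spike-in tags never enter assembly.
    """
    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for t in tags:
        if t.spike:
            continue
        by_key[(t.contig, t.strand)].append(t.pos)

    protos: list[ProtoTFE] = []
    for (contig, strand), positions in sorted(by_key.items()):
        positions.sort()
        run_start = 0
        for i in range(1, len(positions) + 1):
            if i == len(positions) or positions[i] - positions[i - 1] > params.max_gap:
                run = positions[run_start:i]
                if len(run) >= params.min_tags:
                    protos.append(
                        ProtoTFE(contig, strand, run[0], run[-1] + 1, len(run), sample_type)
                    )
                run_start = i
    return protos


def merge_sample_types(
    proto_sets: Mapping[str, Sequence[ProtoTFE]], id_base: int = 1
) -> list[TFE]:
    """Union overlapping per-sample-type clusters into the final TFE set.

    Proto-TFEs sharing >=1 bp on the same contig+strand merge; IDs
    ("FE" + number) are assigned in (contig, start) order from ``id_base``.
    """
    if not proto_sets:
        raise ValueError("at least one proto-TFE set required")
    by_key: dict[tuple[str, str], list[ProtoTFE]] = defaultdict(list)
    for stype, protos in proto_sets.items():
        for p in protos:
            by_key[(p.contig, p.strand)].append(p)

    merged: list[TFE] = []
    for (contig, strand), protos in by_key.items():
        protos.sort(key=lambda p: (p.start, p.end))
        cur_start, cur_end, cur_types = None, None, set()
        for p in protos:
            if cur_start is None:
                cur_start, cur_end, cur_types = p.start, p.end, {p.sample_type}
            elif p.start < cur_end:  # any-bp overlap
                cur_end = max(cur_end, p.end)
                cur_types.add(p.sample_type)
            else:
                merged.append(TFE("", contig, strand, cur_start, cur_end, cur_types))
                cur_start, cur_end, cur_types = p.start, p.end, {p.sample_type}
        if cur_start is not None:
            merged.append(TFE("", contig, strand, cur_start, cur_end, cur_types))

    merged.sort(key=lambda t: (t.contig, t.start, t.strand))
    for i, t in enumerate(merged):
        t.id = f"FE{id_base + i}"
    return merged


def count_per_sample(
    tfes: Sequence[TFE],
    tags: Iterable[AlignedTag],
    known_contigs: Optional[set[str]] = None,
) -> int:
    """Count tags into TFEs in place; returns the number of unassigned tags.

    A tag increments a TFE iff its 5' position lies inside the TFE interval
    on the same contig and strand. Merged TFEs are disjoint per contig+strand
    so each tag lands in at most one feature. Spike tags are ignored.
    """
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list[TFE]]] = {}
    for key, group in _group_by_key(tfes).items():
        group.sort(key=lambda t: t.start)
        starts = np.array([t.start for t in group])
        ends = np.array([t.end for t in group])
        index[key] = (starts, ends, group)

    for t in tfes:
        t.counts = Counter()

    unassigned = 0
    for tag in tags:
        if tag.spike:
            continue
        if known_contigs is not None and tag.contig not in known_contigs:
            raise ValueError(f"tag on unknown contig {tag.contig!r}")
        entry = index.get((tag.contig, tag.strand))
        if entry is None:
            unassigned += 1
            continue
        starts, ends, group = entry
        i = int(np.searchsorted(starts, tag.pos, side="right")) - 1
        if i >= 0 and tag.pos < ends[i]:
            group[i].counts[tag.sample] += 1
        else:
            unassigned += 1
    return unassigned


def find_peak(tfe: TFE, tags: Iterable[AlignedTag]) -> int:
    """Position of maximal tag multiplicity inside the TFE interval.

    Ties break toward the transcription-direction 5'-most position: the
    smallest position on '+', the largest on '-'.
    """
    multiplicity: Counter = Counter()
    for tag in tags:
        if tag.spike or tag.contig != tfe.contig or tag.strand != tfe.strand:
            continue
        if tfe.start <= tag.pos < tfe.end:
            multiplicity[tag.pos] += 1
    if not multiplicity:
        raise ValueError(f"{tfe.id}: no tags in interval")
    best = max(multiplicity.items(), key=lambda kv: (kv[1], -kv[0] if tfe.strand == "+" else kv[0]))
    return best[0]


def assign_peaks(tfes: Sequence[TFE], tags: Sequence[AlignedTag]) -> None:
    """Set ``peak`` on every TFE from one pass over the tags."""
    by_key: dict[tuple[str, str], list[AlignedTag]] = defaultdict(list)
    for tag in tags:
        if not tag.spike:
            by_key[(tag.contig, tag.strand)].append(tag)
    for tfe in tfes:
        tfe.peak = find_peak(tfe, by_key.get((tfe.contig, tfe.strand), []))


def count_matrix(tfes: Sequence[TFE], samples: Sequence[str]) -> pd.DataFrame:
    """TFE x sample integer count matrix."""
    data = {t.id: [t.counts.get(s, 0) for s in samples] for t in tfes}
    return pd.DataFrame.from_dict(data, orient="index", columns=list(samples)).astype(int)


def _group_by_key(tfes: Sequence[TFE]) -> dict[tuple[str, str], list[TFE]]:
    out: dict[tuple[str, str], list[TFE]] = defaultdict(list)
    for t in tfes:
        out[(t.contig, t.strand)].append(t)
    return out
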