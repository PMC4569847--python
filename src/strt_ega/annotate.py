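"""Nine-way genomic annotation of TFEs against transcript models.

A TFE is assigned the first matching class in a fixed priority order:
coding 5'UTR > coding upstream (500 bp) > CDS > coding 3'UTR >
noncoding first exon > noncoding upstream > noncoding other exon >
intron (any transcript) > unannotated. Overlap means >= 1 shared base on
the same strand (the protocol is strand-specific, so opposite-strand
overlap counts as no overlap).
"""
from __future__ import annotations

from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome import TranscriptModel
from .normalize import ExpressionMatrix, content_stage_test
from .tfe import TFE


class AnnotationClass(str, Enum):
    CODING_5UTR = "coding_5utr"
    CODING_UPSTREAM = "coding_upstream"
    CODING_CDS = "coding_cds"
    CODING_3UTR = "coding_3utr"
    NONCODING_FIRST_EXON = "noncoding_first_exon"
    NONCODING_UPSTREAM = "noncoding_upstream"
    NONCODING_OTHER_EXON = "noncoding_other_exon"
    INTRON = "intron"
    UNANNOTATED = "unannotated"


PRIORITY = [c for c in AnnotationClass if c is not AnnotationClass.UNANNOTATED]

# class groups used for stage comparisons of annotation profiles
CLASS_GROUPS = {
    "coding_5prime": (AnnotationClass.CODING_UPSTREAM, AnnotationClass.CODING_5UTR),
    "noncoding_5prime": (
        AnnotationClass.NONCODING_UPSTREAM,
        AnnotationClass.NONCODING_FIRST_EXON,
    ),
    "degradation_like": (
        AnnotationClass.CODING_CDS,
        AnnotationClass.CODING_3UTR,
        AnnotationClass.NONCODING_OTHER_EXON,
    ),
    "intron": (AnnotationClass.INTRON,),
    "unannotated": (AnnotationClass.UNANNOTATED,),
}


def _upstream_interval(t: TranscriptModel, window: int) -> tuple[int, int]:
    """Window of ``window`` bp upstream of the TSS in transcription direction."""
    if t.strand == "+":
        return max(0, t.start - window), t.start
    return t.end, t.end + window


class AnnotationIndex:
    """Strand-aware interval trees over the feature classes of a gene model."""

    def __init__(self, transcripts: Sequence[TranscriptModel], upstream_window: int = 500):
        self.upstream_window = upstream_window
        self._trees: dict[tuple[AnnotationClass, str, str], IntervalTree] = {}
        for t in transcripts:
            if t.coding:
                feats = [
                    (AnnotationClass.CODING_5UTR, t.utr5_intervals()),
                    (AnnotationClass.CODING_UPSTREAM, [_upstream_interval(t, upstream_window)]),
                    (AnnotationClass.CODING_CDS, t.cds_intervals()),
                    (AnnotationClass.CODING_3UTR, t.utr3_intervals()),
                ]
            else:
                first = t.first_exon()
                others = [e for e in t.exons if e != first]
                feats = [
                    (AnnotationClass.NONCODING_FIRST_EXON, [first]),
                    (AnnotationClass.NONCODING_UPSTREAM, [_upstream_interval(t, upstream_window)]),
                    (AnnotationClass.NONCODING_OTHER_EXON, others),
                ]
            feats.append((AnnotationClass.INTRON, t.intron_intervals()))
            for cls, intervals in feats:
                tree = self._trees.setdefault((cls, t.contig, t.strand), IntervalTree())
                for s, e in intervals:
                    if s < e:
                        tree.addi(s, e)

    def classify(self, contig: str, start: int, end: int, strand: str) -> AnnotationClass:
        for cls in PRIORITY:
            tree = self._trees.get((cls, contig, strand))
            if tree is not None and tree.overlaps(start, end):
                return cls
        return AnnotationClass.UNANNOTATED


def classify_tfe(
    tfe: TFE,
    transcripts: Sequence[TranscriptModel] | AnnotationIndex,
    upstream_window: int = 500,
) -> AnnotationClass:
    """Annotation class of one TFE (builds a throwaway index if given a list)."""
    index = (
        transcripts
        if isinstance(transcripts, AnnotationIndex)
        else AnnotationIndex(transcripts, upstream_window)
    )
    return index.classify(tfe.contig, tfe.start, tfe.end, tfe.strand)


def classify_all(
    tfes: Sequence[TFE],
    transcripts: Sequence[TranscriptModel],
    upstream_window: int = 500,
) -> dict[str, AnnotationClass]:
    index = AnnotationIndex(transcripts, upstream_window)
    return {t.id: index.classify(t.contig, t.start, t.end, t.strand) for t in tfes}


def class_proportions(
    matrix: ExpressionMatrix,
    classes: dict[str, AnnotationClass],
    on: str = "expression",
) -> pd.DataFrame:
    """Per-sample fraction of expression (or of detected TFEs) per class.

    ``on="expression"`` weights each TFE by its normalized expression mass;
    ``on="count"`` weights each detected (nonzero) TFE equally. Fractions sum
    to 1 per sample; all-zero samples come back as NaN rows.
    """
    if on not in ("expression", "count"):
        raise ValueError("on must be 'expression' or 'count'")
    values = matrix.values if on == "expression" else (matrix.values > 0).astype(float)
    cls = pd.Series({k: v.value for k, v in classes.items()}).reindex(values.index)
    if cls.isna().any():
        missing = list(cls[cls.isna()].index[:3])
        raise KeyError(f"unclassified TFE(s): {missing}")
    mass = values.groupby(cls, observed=True).sum()  # class x sample
    totals = mass.sum(axis=0)
    fractions = (mass / totals).T  # sample x class
    for c in AnnotationClass:
        if c.value not in fractions.columns:
            fractions[c.value] = 0.0
    fractions.loc[totals == 0, :] = float("nan")
    return fractions[[c.value for c in AnnotationClass]]


def proportion_stage_test(
    fractions: pd.DataFrame,
    stages: pd.Series,
    stage_pair: tuple[str, str],
    class_group: str | Sequence[AnnotationClass],
) -> float:
    """Wilcoxon rank-sum on per-cell grouped class fractions between stages."""
    group = CLASS_GROUPS[class_group] if isinstance(class_group, str) else class_group
    cols = [c.value for c in group]
    summed = fractions[cols].sum(axis=1)
    early, late = stage_pair
    x = summed[stages.reindex(summed.index) == early].dropna()
    y = summed[stages.reindex(summed.index) == late].dropna()
    return content_stage_test(x.to_numpy(), y.to_numpy())
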