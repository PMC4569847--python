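"""Toy/real genome model: contigs, transcript models, repeat intervals.

All coordinates are 0-based half-open on the forward strand of the contig.
Transcript exons are stored in genomic order; "transcription order" reverses
the list on the minus strand.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatInterval:
    contig: str
    start: int
    end: int
    strand: str
    family: str


@dataclass
class TranscriptModel:
    """One transcript: exons, optional CDS, coding flag.

    ``exons`` are 0-based half-open genomic intervals, non-overlapping and
    sorted by start. ``cds`` is a genomic (start, end) pair contained in the
    exon union; ``coding`` is True iff a CDS is present.
    """

    id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: Optional[tuple[int, int]] = None

    @property
    def coding(self) -> bool:
        return self.cds is not None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site (5'-most base)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.id}: empty exon [{s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.id}: exons overlap or are unsorted")
            prev_end = e
        if self.cds is not None:
            cs, ce = self.cds
            covered = sum(max(0, min(e, ce) - max(s, cs)) for s, e in self.exons)
            if cs < self.start or ce > self.end or covered == 0:
                raise ValueError(f"{self.id}: CDS outside exon union")

    def genomic_position(self, offset: int) -> int:
        """Map a transcript-coordinate offset (0 = TSS) to a genomic position.

        Offsets past the transcript end clip to the 3'-most exonic base.
        """
        offset = min(max(offset, 0), self.length - 1)
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for s, e in exons:
            span = e - s
            if offset < span:
                return s + offset if self.strand == "+" else e - 1 - offset
            offset -= span
        raise AssertionError("unreachable")

    def utr5_intervals(self) -> list[tuple[int, int]]:
        """Exonic intervals strictly 5' of the CDS in transcription direction."""
        if self.cds is None:
            return []
        cs, ce = self.cds
        out = []
        for s, e in self.exons:
            if self.strand == "+":
                lo, hi = s, min(e, cs)
            else:
                lo, hi = max(s, ce), e
            if lo < hi:
                out.append((lo, hi))
        return out

    def utr3_intervals(self) -> list[tuple[int, int]]:
        if self.cds is None:
            return []
        cs, ce = self.cds
        out = []
        for s, e in self.exons:
            if self.strand == "+":
                lo, hi = max(s, ce), e
            else:
                lo, hi = s, min(e, cs)
            if lo < hi:
                out.append((lo, hi))
        return out

    def cds_intervals(self) -> list[tuple[int, int]]:
        if self.cds is None:
            return []
        cs, ce = self.cds
        return [(max(s, cs), min(e, ce)) for s, e in self.exons if max(s, cs) < min(e, ce)]

    def intron_intervals(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    def first_exon(self) -> tuple[int, int]:
        """First exon in transcription order."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]


@dataclass
class GenomeModel:
    """Contigs + transcript models + repeat intervals."""

    contigs: list[tuple[str, str]] = field(default_factory=list)
    transcripts: list[TranscriptModel] = field(default_factory=list)
    repeats: list[RepeatInterval] = field(default_factory=list)

    def contig_seq(self, name: str) -> str:
        for n, seq in self.contigs:
            if n == name:
                return seq
        raise KeyError(f"unknown contig {name!r}")

    def contig_lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.contigs}

    def validate(self) -> None:
        lengths = self.contig_lengths()
        for t in self.transcripts:
            t.validate()
            if t.contig not in lengths:
                raise ValueError(f"{t.id}: unknown contig {t.contig}")
            if t.end > lengths[t.contig]:
                raise ValueError(f"{t.id}: exceeds contig bounds")
        for r in self.repeats:
            if r.contig not in lengths or r.start < 0 or r.end > lengths[r.contig]:
                raise ValueError(f"repeat {r} outside contig bounds")
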