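"""Readers and writers for the standard formats used by the pipeline.

All in-memory coordinates are 0-based half-open; GTF (1-based closed) is
converted at the boundary. Tag BED records carry one line per tag:
contig, 5' position, position+1, sample id, 1, strand. Spike-in tags live on
dedicated spike contigs and are flagged on read by contig name.
"""
from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeModel, RepeatInterval, TranscriptModel
from .simulate import SimTruth
from .tfe import TFE, AlignedTag


# --- FASTA ---------------------------------------------------------------

def write_fasta(contigs: Sequence[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


# --- GTF (1-based closed on disk) ----------------------------------------

def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.id}"; transcript_id "{t.id}";'
            for s, e in t.exons:
                fh.write(
                    f"{t.contig}\tstrt_ega\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.cds is not None:
                for s, e in t.cds_intervals():
                    fh.write(
                        f"{t.contig}\tstrt_ega\tCDS\t{s + 1}\t{e}\t0\t{t.strand}\t.\t{attrs}\n"
                    )


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    if os.path.getsize(path) == 0:
        return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tid: dict[str, dict] = {}
    for feat in db.all_features():
        tid = feat.attributes["transcript_id"][0]
        rec = by_tid.setdefault(
            tid, {"contig": feat.seqid, "strand": feat.strand, "exons": [], "cds": []}
        )
        interval = (feat.start - 1, feat.end)  # to 0-based half-open
        if feat.featuretype == "exon":
            rec["exons"].append(interval)
        elif feat.featuretype == "CDS":
            rec["cds"].append(interval)
    out = []
    for tid, rec in by_tid.items():
        exons = sorted(rec["exons"])
        cds = None
        if rec["cds"]:
            cds = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        out.append(TranscriptModel(tid, rec["contig"], rec["strand"], exons, cds))
    out.sort(key=lambda t: t.id)
    return out


# --- BED -----------------------------------------------------------------

def write_bed_tags(tags: Iterable[AlignedTag], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f"{t.contig}\t{t.pos}\t{t.pos + 1}\t{t.sample}\t1\t{t.strand}\n")


def read_bed_tags(path: str | Path, spike_contigs: Sequence[str] = ()) -> list[AlignedTag]:
    spikes = set(spike_contigs)
    if os.path.getsize(path) == 0:
        return []
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
        dtype={"contig": str, "name": str},
    )
    return [
        AlignedTag(r.contig, int(r.start), r.strand, r.name, spike=r.contig in spikes)
        for r in df.itertuples()
    ]


def write_bed_repeats(repeats: Sequence[RepeatInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.family}\t0\t{r.strand}\n")


def read_bed_repeats(path: str | Path) -> list[RepeatInterval]:
    if os.path.getsize(path) == 0:
        return []
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "family", "score", "strand"],
        dtype={"contig": str, "family": str},
    )
    return [
        RepeatInterval(r.contig, int(r.start), int(r.end), r.strand, r.family)
        for r in df.itertuples()
    ]


def write_bed_tfes(tfes: Sequence[TFE], path: str | Path) -> None:
    """BED6+ with peak and total count as extra columns."""
    with open(path, "w") as fh:
        for t in sorted(tfes, key=lambda t: (t.contig, t.start)):
            peak = t.peak if t.peak is not None else -1
            fh.write(
                f"{t.contig}\t{t.start}\t{t.end}\t{t.id}\t{t.total_count}\t{t.strand}"
                f"\t{peak}\t{','.join(sorted(t.sample_types))}\n"
            )


# --- sample sheet / truth ------------------------------------------------

def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet[["sample_id", "stage", "well_barcode"]].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)


def read_truth(path: str | Path) -> SimTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SimTruth(**d)


# --- alignment ingestion --------------------------------------------------

def read_alignments(
    path: str | Path,
    spike_contigs: Sequence[str] = (),
    max_clip5: int = 3,
    default_sample: str = "sample",
) -> list[AlignedTag]:
    """Reduce alignments to strand-aware 5'-end tags.

    BED6 input is taken at face value. For SAM/BAM, each primary alignment
    contributes its read 5' end on the reference: the leftmost aligned base
    on '+', the rightmost on '-' (second-strand protocol: read strand equals
    transcript strand). Secondary/supplementary/unmapped records are
    dropped, as are reads soft-clipped by more than ``max_clip5`` bases at
    the 5' end (the clip would shift the inferred start). The sample
    identity comes from the read group, falling back to ``default_sample``.
    """
    path = str(path)
    if path.endswith(".bed"):
        return read_bed_tags(path, spike_contigs)
    if not (path.endswith(".bam") or path.endswith(".sam")):
        raise ValueError(f"unknown alignment format: {path}")
    spikes = set(spike_contigs)
    mode = "rb" if path.endswith(".bam") else "r"
    tags = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cigar = rec.cigartuples or []
            if rec.is_reverse:
                pos = rec.reference_end - 1
                clip5 = cigar[-1][1] if cigar and cigar[-1][0] == 4 else 0
            else:
                pos = rec.reference_start
                clip5 = cigar[0][1] if cigar and cigar[0][0] == 4 else 0
            if clip5 > max_clip5:
                continue
            sample = rec.get_tag("RG") if rec.has_tag("RG") else default_sample
            contig = rec.reference_name
            tags.append(
                AlignedTag(contig, pos, "-" if rec.is_reverse else "+", str(sample),
                           spike=contig in spikes)
            )
    return tags


# --- fixture bundle -------------------------------------------------------

FIXTURE_FILES = {
    "genome": "genome.fa",
    "gtf": "genes.gtf",
    "repeats": "repeats.bed",
    "tags": "tags.bed",
    "sheet": "samples.tsv",
    "truth": "truth.json",
}


def write_fixtures(
    genome: GenomeModel,
    tags: Sequence[AlignedTag],
    sheet: pd.DataFrame,
    truth: Optional[SimTruth],
    directory: str | Path,
) -> dict[str, Path]:
    """Write the complete simulated experiment as plain-text fixtures."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}
    try:
        write_fasta(genome.contigs, paths["genome"])
        write_gtf(genome.transcripts, paths["gtf"])
        write_bed_repeats(genome.repeats, paths["repeats"])
        write_bed_tags(tags, paths["tags"])
        write_sample_sheet(sheet, paths["sheet"])
        if truth is not None:
            write_truth(truth, paths["truth"])
        else:
            paths.pop("truth")
    except OSError as exc:
        raise OSError(f"failed writing fixtures under {directory}: {exc}") from exc
    return paths


def read_fixtures(directory: str | Path, spike_contigs: Sequence[str]) -> dict:
    directory = Path(directory)
    contigs = read_fasta(directory / FIXTURE_FILES["genome"])
    genome = GenomeModel(
        contigs,
        read_gtf(directory / FIXTURE_FILES["gtf"]),
        read_bed_repeats(directory / FIXTURE_FILES["repeats"]),
    )
    tags = read_bed_tags(directory / FIXTURE_FILES["tags"], spike_contigs)
    sheet = read_sample_sheet(directory / FIXTURE_FILES["sheet"])
    truth_path = directory / FIXTURE_FILES["truth"]
    truth = read_truth(truth_path) if truth_path.exists() else None
    return {"genome": genome, "tags": tags, "sheet": sheet, "truth": truth}
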