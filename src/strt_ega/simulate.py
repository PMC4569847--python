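"""Synthetic staged single-cell 5'-tag experiments with known ground truth.

The generator emulates the statistical structure of a 5'-capturing,
spike-in-calibrated single-cell protocol applied to cleavage-stage embryos:

* staged cells (oocyte -> zygote -> 4-cell -> 8-cell) whose per-cell
  poly(A) mRNA molecule budget halves with each division;
* active maternal degradation that 5'-truncates a configurable fraction of
  maternal molecules, moving their captured 5' ends into internal
  exons / CDS / 3'UTR;
* stage-activated embryonic genes whose promoter windows carry a planted
  motif, positioned inside planted Alu-like repeats when configured;
* a constant spike-in molecule count per well (8 spike species with fixed
  relative abundances) and binomial capture/sampling noise.

Everything planted (TSS positions, expected molecule counts, DE labels,
motif and repeat coordinates) is returned in a :class:`SimTruth` record for
parameter-recovery tests.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, RepeatInterval, TranscriptModel, revcomp
from .tfe import AlignedTag

BASES = np.frombuffer(b"ACGT", dtype="S1")

SPIKE_NAMES = tuple(f"SPIKE_{i}" for i in range(1, 9))
# fixed relative abundances of the eight spike species (sum to 1)
SPIKE_WEIGHTS = (0.30, 0.20, 0.15, 0.10, 0.10, 0.07, 0.05, 0.03)
SPIKE_LENGTH = 500

ALU_FAMILIES = ("AluY", "AluSx", "AluJb")
REPEAT_LENGTH = 300

# toy gene layout: one gene per fixed-width slot, promoter space on the
# transcription-upstream side of the slot
SLOT = 7000
MARGIN = 3000
PROMOTER_UP = 2000
PROMOTER_DOWN = 500


def default_motif_pwm(width: int = 12, consensus: str = "TAATCCCAGCAC") -> np.ndarray:
    """An informative default PWM (~1.5 bits/column) around a PRD-like core."""
    consensus = (consensus * (width // len(consensus) + 1))[:width]
    pwm = np.full((width, 4), 0.03)
    for i, b in enumerate(consensus):
        pwm[i, "ACGT".index(b)] = 0.91
    return pwm


@dataclass
class StageSpec:
    name: str
    n_cells: int
    mrna_budget: int  # poly(A) molecules per cell


@dataclass
class DegradationModel:
    """Active maternal-degradation model.

    ``fractions`` maps stage name -> fraction of maternal molecules whose 5'
    end is moved downstream; the truncation offset (in transcript
    coordinates) is geometric with the given mean, or a constant for
    degenerate test cases.
    """

    fractions: dict[str, float] = field(default_factory=dict)
    mean_offset: float = 300.0
    dist: str = "geometric"  # "geometric" | "constant"

    def fraction_for(self, stage: str) -> float:
        return self.fractions.get(stage, 0.0)

    def draw_offsets(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n == 0:
            return np.zeros(0, dtype=int)
        if self.dist == "geometric":
            return rng.geometric(min(1.0, 1.0 / self.mean_offset), size=n)
        if self.dist == "constant":
            return np.full(n, int(self.mean_offset))
        raise ValueError(f"unknown offset distribution {self.dist!r}")


@dataclass
class SimConfig:
    """Study-condition parameters for the toy genome and experiment."""

    stages: list[StageSpec] = field(
        default_factory=lambda: [
            StageSpec("oocyte", 12, 100_000),
            StageSpec("4cell", 12, 25_000),
        ]
    )
    n_genes: int = 100
    frac_noncoding: float = 0.2
    spike_molecules: int = 1000  # per well, summed over the 8 spike species
    capture_efficiency: float = 0.1
    degradation: DegradationModel = field(
        default_factory=lambda: DegradationModel({"4cell": 0.3, "8cell": 0.3})
    )
    # stage name -> gene indices activated at (and after) that stage
    ega_genes: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"4cell": tuple(range(10))}
    )
    activation_fold: float = 8.0
    motif_pwm: Optional[np.ndarray] = None
    plant_motif_in_repeat: bool = True
    promoter_repeat_density: float = 2.0  # planted repeats per activated promoter
    background_repeat_density: float = 1.1  # expected repeats per 2,500-bp window
    expression_sigma: float = 1.0  # lognormal spread of baseline gene weights
    contig_length: Optional[int] = None  # None -> auto-sized
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for frac in (self.frac_noncoding, self.capture_efficiency, *self.degradation.fractions.values()):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        for st in self.stages:
            if st.mrna_budget < 0 or st.n_cells < 0:
                raise ValueError("budgets and cell counts must be non-negative")
        for stage in self.ega_genes:
            if stage not in [s.name for s in self.stages]:
                raise ValueError(f"EGA stage {stage!r} not in stage design")

    @property
    def pwm(self) -> np.ndarray:
        return self.motif_pwm if self.motif_pwm is not None else default_motif_pwm()

    def activated_genes(self) -> tuple[int, ...]:
        out: set[int] = set()
        for genes in self.ega_genes.values():
            out.update(genes)
        return tuple(sorted(out))


@dataclass
class SimTruth:
    """Ground truth planted by the generator."""

    tss: dict[str, int]
    expected_molecules: dict[str, dict[str, float]]  # stage -> transcript -> per-cell mean
    de_labels: dict[str, dict[str, str]]  # "early:late" -> transcript -> up/down/none
    motif_instances: list[dict]
    promoter_repeats: list[dict]
    degradation_fractions: dict[str, float]


def truncate_maternal(
    offsets: np.ndarray,
    lengths: np.ndarray,
    fraction: float,
    model: DegradationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move the 5' end of a random fraction of molecules downstream.

    ``offsets`` are transcript-coordinate 5' offsets (0 = intact at the TSS);
    draws are clipped to the last transcript base, so extreme offsets land at
    the 3'-most exonic position.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("truncation fraction must be in [0, 1]")
    out = np.asarray(offsets).copy()
    if fraction == 0.0 or out.size == 0:
        return out
    mask = rng.random(out.size) < fraction
    draws = model.draw_offsets(int(mask.sum()), rng)
    out[mask] = np.minimum(out[mask] + draws, np.asarray(lengths)[mask] - 1)
    return out


def _promoter_window(tss: int, strand: str, contig_len: int) -> tuple[int, int]:
    if strand == "+":
        lo, hi = tss - PROMOTER_UP, tss + PROMOTER_DOWN
    else:
        lo, hi = tss - PROMOTER_DOWN + 1, tss + PROMOTER_UP + 1
    return max(0, lo), min(contig_len, hi)


def _sample_site(pwm: np.ndarray, rng: np.random.Generator) -> str:
    return "".join("ACGT"[rng.choice(4, p=row / row.sum())] for row in pwm)


def build_toy_genome(config: SimConfig) -> GenomeModel:
    """Build a toy genome whose activated-gene promoters carry planted
    Alu-like repeats (at the configured density) and >=1 motif instance.

    Planted coordinates are recorded on ``genome.meta`` and copied into the
    :class:`SimTruth` by :func:`simulate_experiment`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    required = 2 * MARGIN + n * SLOT
    length = config.contig_length if config.contig_length is not None else required
    if length < required:
        raise ValueError(
            f"contig length {length} too short for {n} genes (need {required})"
        )
    contig = "chr_sim"
    seq = rng.integers(0, 4, size=length)

    transcripts: list[TranscriptModel] = []
    windows: dict[str, tuple[int, int]] = {}
    for i in range(n):
        base = MARGIN + i * SLOT
        strand = "+" if i % 2 == 0 else "-"
        coding = rng.random() >= config.frac_noncoding
        if strand == "+":
            tss = base + 2600
            exons = [(tss, tss + 200), (tss + 500, tss + 900), (tss + 1200, tss + 1600)]
            cds = (tss + 100, tss + 1500) if coding else None
        else:
            tes = base + 2600  # 3'-most base + 1 after mirroring
            exons = [(tes, tes + 400), (tes + 700, tes + 1100), (tes + 1400, tes + 1600)]
            cds = (tes + 100, tes + 1500) if coding else None
        t = TranscriptModel(f"G{i:04d}", contig, strand, exons, cds)
        transcripts.append(t)
        windows[t.id] = _promoter_window(t.tss, strand, length)

    # Alu-like family consensus sequences, copied with 10% divergence
    consensi = {
        fam: rng.integers(0, 4, size=REPEAT_LENGTH) for fam in ALU_FAMILIES
    }

    def write_repeat(start: int, fam: str) -> None:
        copy = consensi[fam].copy()
        mut = rng.random(REPEAT_LENGTH) < 0.10
        copy[mut] = rng.integers(0, 4, size=int(mut.sum()))
        seq[start : start + REPEAT_LENGTH] = copy

    activated = [transcripts[i] for i in config.activated_genes()]
    activated_windows = [windows[t.id] for t in activated]
    repeats: list[RepeatInterval] = []
    promoter_repeats: list[dict] = []

    for t in activated:
        ws, we = windows[t.id]
        k = rng.poisson(config.promoter_repeat_density)
        for _ in range(k):
            if we - ws < REPEAT_LENGTH:
                break
            start = int(rng.integers(ws, we - REPEAT_LENGTH + 1))
            fam = ALU_FAMILIES[rng.choice(len(ALU_FAMILIES))]
            rstrand = "+" if rng.random() < 0.5 else "-"
            write_repeat(start, fam)
            r = RepeatInterval(contig, start, start + REPEAT_LENGTH, rstrand, fam)
            repeats.append(r)
            promoter_repeats.append(
                {"transcript": t.id, "contig": contig, "start": start,
                 "end": start + REPEAT_LENGTH, "strand": rstrand, "family": fam}
            )

    # background repeats everywhere except activated promoter windows,
    # at the configured density per 2,500-bp of available sequence
    available = length - sum(we - ws for ws, we in activated_windows)
    n_bg = rng.poisson(max(available, 0) * config.background_repeat_density / 2500.0)
    placed = 0
    attempts = 0
    while placed < n_bg and attempts < 20 * n_bg + 100:
        attempts += 1
        start = int(rng.integers(0, length - REPEAT_LENGTH + 1))
        if any(start < we and start + REPEAT_LENGTH > ws for ws, we in activated_windows):
            continue
        fam = ALU_FAMILIES[rng.choice(len(ALU_FAMILIES))]
        rstrand = "+" if rng.random() < 0.5 else "-"
        write_repeat(start, fam)
        repeats.append(RepeatInterval(contig, start, start + REPEAT_LENGTH, rstrand, fam))
        placed += 1

    # plant one motif instance per activated promoter
    pwm = config.pwm
    W = pwm.shape[0]
    motif_instances: list[dict] = []
    by_promoter: dict[str, list[dict]] = {}
    for pr in promoter_repeats:
        by_promoter.setdefault(pr["transcript"], []).append(pr)
    for t in activated:
        ws, we = windows[t.id]
        gstart = None
        if config.plant_motif_in_repeat and by_promoter.get(t.id):
            pr = by_promoter[t.id][0]
            lo, hi = max(pr["start"], ws), min(pr["end"], we) - W
            if lo <= hi:
                gstart = int(rng.integers(lo, hi + 1))
        if gstart is None:
            gstart = int(rng.integers(ws, we - W + 1))
        site = _sample_site(pwm, rng)
        planted = site if t.strand == "+" else revcomp(site)
        seq[gstart : gstart + W] = [b"ACGT".index(c.encode()) for c in planted]
        offset = gstart - ws if t.strand == "+" else we - gstart - W
        motif_instances.append(
            {"transcript": t.id, "contig": contig, "start": gstart, "end": gstart + W,
             "strand": t.strand, "window_offset": int(offset), "site": site}
        )

    contig_seq = BASES[seq].tobytes().decode()
    contigs = [(contig, contig_seq)]
    # spike reference contigs (no transcripts; tags land at position 0)
    spike_rng = np.random.default_rng([config.seed, 7])
    for name in SPIKE_NAMES:
        contigs.append((name, BASES[spike_rng.integers(0, 4, SPIKE_LENGTH)].tobytes().decode()))

    genome = GenomeModel(contigs, transcripts, sorted(repeats, key=lambda r: (r.contig, r.start)))
    genome.validate()
    genome.meta = {  # type: ignore[attr-defined]
        "motif_instances": motif_instances,
        "promoter_repeats": promoter_repeats,
        "promoter_windows": {k: list(v) for k, v in windows.items()},
        "activated": [t.id for t in activated],
    }
    return genome


def _spike_allocation(total: int) -> list[int]:
    counts = [int(np.floor(total * w)) for w in SPIKE_WEIGHTS]
    for i in range(total - sum(counts)):
        counts[i % len(counts)] += 1
    return counts


def _stage_weights(config: SimConfig, base: np.ndarray, stage_idx: int) -> np.ndarray:
    """Expression weights at a stage: EGA genes sit ``fold`` below their
    activated level until their activation stage is reached."""
    stage_names = [s.name for s in config.stages]
    w = base.copy()
    for stage, genes in config.ega_genes.items():
        k = stage_names.index(stage)
        factor = 1.0 if stage_idx >= k else 1.0 / config.activation_fold
        for g in genes:
            w[g] = base[g] * factor
    return w


def simulate_experiment(
    genome: GenomeModel, config: SimConfig
) -> tuple[list[AlignedTag], pd.DataFrame, SimTruth]:
    """Simulate captured 5' tags for every cell of every stage.

    Intact molecules yield tags exactly at the planted TSS; truncated
    maternal molecules yield internal/3'-shifted tags; spike tags are
    binomial draws from the fixed per-well molecule count.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    transcripts = genome.transcripts
    n = len(transcripts)
    base = np.exp(rng.normal(0.0, config.expression_sigma, size=n))
    ega_all = set(config.activated_genes())
    maternal = np.array([i not in ega_all for i in range(n)])
    lengths = np.array([t.length for t in transcripts])
    spike_counts = _spike_allocation(config.spike_molecules)

    if config.capture_efficiency == 0.0 and any(
        s.mrna_budget > 0 and s.n_cells > 0 for s in config.stages
    ):
        warnings.warn("capture efficiency 0 with nonzero budget: no genomic tags")

    tags: list[AlignedTag] = []
    sheet_rows = []
    expected: dict[str, dict[str, float]] = {}
    well = 0
    for si, stage in enumerate(config.stages):
        w = _stage_weights(config, base, si)
        probs = w / w.sum()
        expected[stage.name] = {
            t.id: float(stage.mrna_budget * probs[i]) for i, t in enumerate(transcripts)
        }
        frac = config.degradation.fraction_for(stage.name)
        for c in range(stage.n_cells):
            sample = f"{stage.name}_{c:02d}"
            sheet_rows.append(
                {"sample_id": sample, "stage": stage.name, "well_barcode": _barcode(well)}
            )
            well += 1
            molecules = rng.multinomial(stage.mrna_budget, probs)
            captured = rng.binomial(molecules, config.capture_efficiency)
            for i, t in enumerate(transcripts):
                k = int(captured[i])
                if k == 0:
                    continue
                offsets = np.zeros(k, dtype=int)
                if maternal[i] and frac > 0.0:
                    offsets = truncate_maternal(
                        offsets, np.full(k, lengths[i]), frac, config.degradation, rng
                    )
                for off, mult in zip(*np.unique(offsets, return_counts=True)):
                    pos = t.tss if off == 0 else t.genomic_position(int(off))
                    tags.extend(
                        [AlignedTag(t.contig, pos, t.strand, sample)] * int(mult)
                    )
            for name, nk in zip(SPIKE_NAMES, spike_counts):
                ks = int(rng.binomial(nk, config.capture_efficiency))
                tags.extend([AlignedTag(name, 0, "+", sample, spike=True)] * ks)

    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "stage", "well_barcode"])
    meta = getattr(genome, "meta", {})
    truth = SimTruth(
        tss={t.id: t.tss for t in transcripts},
        expected_molecules=expected,
        de_labels=_de_labels(config, expected),
        motif_instances=list(meta.get("motif_instances", [])),
        promoter_repeats=list(meta.get("promoter_repeats", [])),
        degradation_fractions=dict(config.degradation.fractions),
    )
    return tags, sheet, truth


def _de_labels(config: SimConfig, expected: dict[str, dict[str, float]]) -> dict[str, dict[str, str]]:
    """Per-transition truth labels.

    "up": embryonic activation at the later stage (absolute per-cell
    molecules of the gene rise or the gene enters its activated level);
    "down": maternal gene whose active degradation fraction increases, i.e.
    its intact-TSS signal falls beyond pure dilution.
    """
    labels: dict[str, dict[str, str]] = {}
    stage_names = [s.name for s in config.stages]
    ega_all = set(config.activated_genes())
    for a, b in zip(stage_names, stage_names[1:]):
        key = f"{a}:{b}"
        later_activated = set()
        for stage, genes in config.ega_genes.items():
            ka = stage_names.index(stage)
            if stage_names.index(a) < ka <= stage_names.index(b):
                later_activated.update(genes)
        fa = config.degradation.fraction_for(a)
        fb = config.degradation.fraction_for(b)
        lab = {}
        for i, tid in enumerate(sorted(expected[a])):
            if i in later_activated:
                lab[tid] = "up"
            elif i not in ega_all and fb > fa:
                lab[tid] = "down"
            else:
                lab[tid] = "none"
        labels[key] = lab
    return labels


def _barcode(well: int) -> str:
    letters = "ACGT"
    return "".join(letters[(well >> (2 * k)) & 3] for k in range(6))


def simulate_de_counts(
    n_tfes: int = 500,
    n1: int = 12,
    n2: int = 12,
    n_up: int = 0,
    fold: float = 8.0,
    dilution: float = 1.0,
    base_mean: float = 20.0,
    sigma: float = 1.0,
    spike_base: int = 1000,
    depth_cv: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, set[str]]:
    """Count-level simulator for the differential test.

    Per-feature expected counts are lognormal around ``base_mean``; raw
    counts are Poisson, scaled by a per-sample sequencing-depth factor that
    also scales the spike-in depth. The first ``n_up`` features are ``fold``
    higher in group 2; ``dilution`` divides every group-2 expectation
    (per-cell content reduction by cleavage).

    Returns (counts, spike_depths, group labels, set of planted up ids).
    """
    rng = np.random.default_rng(seed)
    mu = base_mean * np.exp(rng.normal(0.0, sigma, size=n_tfes) - sigma**2 / 2)
    samples = [f"A_{i:02d}" for i in range(n1)] + [f"B_{i:02d}" for i in range(n2)]
    depth = np.exp(rng.normal(0.0, depth_cv, size=n1 + n2))
    group = pd.Series(["A"] * n1 + ["B"] * n2, index=samples, name="stage")
    mu_mat = np.tile(mu[:, None], (1, n1 + n2)).astype(float)
    mu_mat[:n_up, n1:] *= fold
    mu_mat[:, n1:] /= dilution
    counts = rng.poisson(mu_mat * depth[None, :])
    ids = [f"FE{i + 1}" for i in range(n_tfes)]
    counts_df = pd.DataFrame(counts, index=ids, columns=samples)
    spikes = pd.Series(np.rint(spike_base * depth).astype(int), index=samples, name="spike_reads")
    return counts_df, spikes, group, set(ids[:n_up])
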