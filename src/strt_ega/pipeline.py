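"""Configuration and orchestration of the analysis stage graph.

Stage order: qc -> tfe -> normalize -> {annotate, de, cluster} -> motifs.
Each stage reads the fixture files plus upstream artifacts from the output
directory and writes plain-text artifacts; a run manifest records
parameters, the seed and input checksums so identical configurations
reproduce identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import cluster as clu
from . import io as sio
from . import motifs as mot
from . import normalize as norm
from . import qc as sqc
from . import tfe as stfe
from .diffexp import DEParams, call_de
from .simulate import SPIKE_NAMES

log = logging.getLogger("strt_ega")

STAGE_ORDER = ["qc", "tfe", "normalize", "annotate", "de", "cluster", "motifs"]
DEPENDENCIES = {
    "qc": [],
    "tfe": ["qc"],
    "normalize": ["tfe"],
    "annotate": ["normalize"],
    "de": ["normalize"],
    "cluster": ["normalize"],
    "motifs": ["de"],
}
ARTIFACTS = {
    "qc": ["qc_table.tsv", "qc_kept.tsv"],
    "tfe": ["tfes.bed", "tfe_counts.tsv"],
    "normalize": ["expression.tsv", "spike_depths.tsv", "rna_content.tsv"],
    "annotate": ["tfe_classes.tsv", "class_fractions.tsv"],
    "de": ["de_results.tsv"],
    "cluster": ["correlation.tsv", "dendrogram.nwk", "outliers.tsv"],
    "motifs": ["promoters.fa", "promoters.bed", "motif.meme.txt", "motif_hits.tsv",
               "alu_enrichment.json"],
}


@dataclass
class RunConfig:
    """Paths + per-stage parameters for one pipeline run."""

    fixtures_dir: str
    out_dir: str
    seed: int = 0
    spike_contigs: tuple[str, ...] = SPIKE_NAMES
    # qc
    min_raw_reads: int = 100_000
    min_spike_reads: int = 50
    k_sd: float = 2.0
    # tfe
    min_tags: int = 5
    max_gap: int = 60
    # de
    transition: Optional[tuple[str, str]] = None  # default: first two stages
    divisions: int = 4
    resamples: int = 20
    permutations: int = 1000
    q_threshold: float = 0.05
    # annotate
    upstream_window: int = 500
    # cluster
    min_pairs: int = 30
    bootstrap: int = 100
    consensus: float = 0.7
    # motifs
    motif_width: int = 12
    scan_p_threshold: float = 1e-10
    alu_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "transition" in raw and raw["transition"] is not None:
            raw["transition"] = tuple(raw["transition"])
        if "spike_contigs" in raw:
            raw["spike_contigs"] = tuple(raw["spike_contigs"])
        return cls(**raw)

    def validate_paths(self) -> None:
        missing = [
            str(Path(self.fixtures_dir) / f)
            for f in ("genome.fa", "genes.gtf", "repeats.bed", "tags.bed", "samples.tsv")
            if not (Path(self.fixtures_dir) / f).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages: Optional[Sequence[str]] = None) -> Path:
    """Run the requested stages (default: all) in dependency order."""
    config.validate_paths()
    requested = list(stages) if stages else list(STAGE_ORDER)
    for s in requested:
        if s not in STAGE_ORDER:
            raise ValueError(f"unknown stage {s!r}")
    requested = [s for s in STAGE_ORDER if s in requested]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for s in requested:
        for dep in DEPENDENCIES[s]:
            if dep in requested:
                continue
            if not all((out / f).exists() for f in ARTIFACTS[dep]):
                raise RuntimeError(f"stage {s!r} needs artifacts of {dep!r}: run {dep!r} first")

    data = sio.read_fixtures(config.fixtures_dir, config.spike_contigs)
    genome, tags, sheet = data["genome"], data["tags"], data["sheet"]
    state: dict = {}
    for s in requested:
        log.info("stage %s: parameters %s", s, _stage_params(config, s))
        _STAGE_FUNCS[s](config, out, genome, tags, sheet, state)

    manifest = {
        "stages": requested,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("fixtures_dir", "out_dir")
        },
        "inputs": {
            f: _sha256(Path(config.fixtures_dir) / f)
            for f in ("genome.fa", "genes.gtf", "repeats.bed", "tags.bed", "samples.tsv")
        },
        "artifacts": {s: ARTIFACTS[s] for s in requested},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _stage_params(config: RunConfig, stage: str) -> dict:
    keys = {
        "qc": ["min_raw_reads", "min_spike_reads", "k_sd"],
        "tfe": ["min_tags", "max_gap"],
        "normalize": [],
        "annotate": ["upstream_window"],
        "de": ["transition", "divisions", "resamples", "permutations", "q_threshold"],
        "cluster": ["min_pairs", "bootstrap", "consensus"],
        "motifs": ["motif_width", "scan_p_threshold", "alu_permutations"],
    }[stage]
    return {k: getattr(config, k) for k in keys}


def _kept_samples(out: Path) -> list[str]:
    return pd.read_csv(out / "qc_kept.tsv", sep="\t", dtype=str)["sample_id"].tolist()


def _stage_qc(config, out, genome, tags, sheet, state) -> None:
    thr = sqc.QCThresholds(config.min_raw_reads, config.min_spike_reads, config.k_sd)
    samples = sqc.qc_from_tags(tags, sheet)
    kept, _ = sqc.prefilter_samples(samples, thr)
    kept, _, stats = sqc.adaptive_exclusion(kept, thr)
    sqc.qc_table(samples).to_csv(out / "qc_table.tsv", sep="\t", index=False)
    pd.DataFrame({"sample_id": [s.sample for s in kept]}).to_csv(
        out / "qc_kept.tsv", sep="\t", index=False
    )
    with open(out / "qc_stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)


def _stage_tfe(config, out, genome, tags, sheet, state) -> None:
    kept = set(_kept_samples(out))
    stage_of = dict(zip(sheet["sample_id"], sheet["stage"]))
    tags = [t for t in tags if t.sample in kept]
    params = stfe.AssemblyParams(config.min_tags, config.max_gap)
    protos = {}
    for stype in sheet["stage"].unique():
        stype_tags = [t for t in tags if stage_of[t.sample] == stype]
        protos[stype] = stfe.cluster_tags(stype_tags, params, stype)
    tfes = stfe.merge_sample_types(protos)
    known = {name for name, _ in genome.contigs}
    stfe.count_per_sample(tfes, tags, known_contigs=known)
    stfe.assign_peaks(tfes, tags)
    sio.write_bed_tfes(tfes, out / "tfes.bed")
    samples = [s for s in sheet["sample_id"] if s in kept]
    stfe.count_matrix(tfes, samples).to_csv(out / "tfe_counts.tsv", sep="\t")
    state["tfes"] = tfes


def _stage_normalize(config, out, genome, tags, sheet, state) -> None:
    from collections import Counter

    counts = pd.read_csv(out / "tfe_counts.tsv", sep="\t", index_col=0)
    kept = list(counts.columns)
    spike_c: Counter = Counter()
    genomic_c: Counter = Counter()
    for t in tags:
        (spike_c if t.spike else genomic_c)[t.sample] += 1
    spike = pd.Series([spike_c.get(s, 0) for s in kept], index=kept, dtype=int)
    genomic = pd.Series([genomic_c.get(s, 0) for s in kept], index=kept, dtype=int)
    stages = pd.Series(
        dict(zip(sheet["sample_id"], sheet["stage"])), name="stage"
    ).reindex(kept)
    em = norm.spikein_normalize(counts, spike, stages)
    em.values.to_csv(out / "expression.tsv", sep="\t")
    pd.DataFrame(
        {"sample_id": kept, "spike_reads": spike, "genomic_reads": genomic,
         "stage": stages}
    ).to_csv(out / "spike_depths.tsv", sep="\t", index=False)
    stage_list = list(dict.fromkeys(sheet["stage"]))
    content_tbl = pd.DataFrame(
        {"sample_id": kept, "stage": stages, "genomic_tags": genomic, "spike_tags": spike}
    )
    if len(stage_list) >= 2:
        pair = (stage_list[0], stage_list[1])
        content = norm.rna_content(content_tbl, pair)
        x = content.loc[content["stage"] == pair[0], "centered_ratio"]
        y = content.loc[content["stage"] == pair[1], "centered_ratio"]
        content["wilcoxon_p"] = norm.content_stage_test(x, y)
        content.to_csv(out / "rna_content.tsv", sep="\t", index=False)
    else:
        content_tbl.to_csv(out / "rna_content.tsv", sep="\t", index=False)
    state["matrix"] = em


def _load_matrix(out: Path) -> norm.ExpressionMatrix:
    values = pd.read_csv(out / "expression.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(out / "spike_depths.tsv", sep="\t", index_col=0)
    return norm.ExpressionMatrix(
        values, meta["spike_reads"].reindex(values.columns),
        meta["stage"].reindex(values.columns)
    )


def _load_tfes(out: Path) -> list[stfe.TFE]:
    tfes = []
    with open(out / "tfes.bed") as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            t = stfe.TFE(f[3], f[0], f[5], int(f[1]), int(f[2]),
                         set(f[7].split(",")) if len(f) > 7 and f[7] else set())
            t.peak = int(f[6]) if len(f) > 6 else None
            tfes.append(t)
    return tfes


def _stage_annotate(config, out, genome, tags, sheet, state) -> None:
    em = state.get("matrix") or _load_matrix(out)
    tfes = state.get("tfes") or _load_tfes(out)
    classes = ann.classify_all(tfes, genome.transcripts, config.upstream_window)
    pd.Series({k: v.value for k, v in classes.items()}, name="class").rename_axis(
        "tfe"
    ).to_csv(out / "tfe_classes.tsv", sep="\t")
    fractions = ann.class_proportions(em, classes)
    fractions.rename_axis("sample_id").to_csv(out / "class_fractions.tsv", sep="\t")
    state["classes"] = classes


def _stage_de(config, out, genome, tags, sheet, state) -> None:
    em = state.get("matrix") or _load_matrix(out)
    stage_list = list(dict.fromkeys(sheet["stage"]))
    transition = config.transition or (stage_list[0], stage_list[1])
    params = DEParams(config.resamples, config.permutations, config.divisions,
                      config.q_threshold, config.seed)
    res = call_de(em, tuple(transition), params)
    res.to_csv(out / "de_results.tsv", sep="\t")
    state["de"] = res


def _stage_cluster(config, out, genome, tags, sheet, state) -> None:
    em = state.get("matrix") or _load_matrix(out)
    cm = clu.masked_spearman(em.values, config.min_pairs)
    cm.corr.to_csv(out / "correlation.tsv", sep="\t")
    _, _, newick = clu.hcluster(cm)
    (out / "dendrogram.nwk").write_text(newick + "\n")
    rng = np.random.default_rng(config.seed)
    flags = clu.bootstrap_outliers(
        em.values, em.stages, config.bootstrap, config.consensus, config.min_pairs, rng
    )
    flags.rename_axis("sample_id").to_csv(out / "outliers.tsv", sep="\t")


def _stage_motifs(config, out, genome, tags, sheet, state) -> None:
    de = state.get("de")
    if de is None:
        de = pd.read_csv(out / "de_results.tsv", sep="\t", index_col=0)
    tfes = {t.id: t for t in (state.get("tfes") or _load_tfes(out))}
    up_ids = list(de.index[de["direction"] == "up"])
    windows = [mot.extract_promoter(tfes[i], genome) for i in up_ids if i in tfes]
    if not windows:
        (out / "motif_hits.tsv").write_text("promoter\toffset\tscore\tpvalue\n")
        (out / "alu_enrichment.json").write_text("{}\n")
        (out / "promoters.fa").write_text("")
        (out / "promoters.bed").write_text("")
        (out / "motif.meme.txt").write_text("")
        log.warning("no upregulated TFEs: motif stage produced empty outputs")
        return
    sio.write_fasta([(w.tfe_id, w.seq) for w in windows], out / "promoters.fa")
    with open(out / "promoters.bed", "w") as fh:
        for w in windows:
            fh.write(f"{w.contig}\t{w.start}\t{w.end}\t{w.tfe_id}\t0\t{w.strand}\n")
    rng = np.random.default_rng(config.seed)
    result = mot.zoops_em_discover(windows, config.motif_width, rng=rng)
    (out / "motif.meme.txt").write_text(pwm_to_meme(result.pwm, "MOTIF_1"))
    bg = np.bincount(
        np.concatenate([mot.encode(w.seq) for w in windows]), minlength=4
    ).astype(float)
    bg /= bg.sum()
    with open(out / "motif_hits.tsv", "w") as fh:
        fh.write("promoter\toffset\tscore\tpvalue\n")
        for w in windows:
            hit = mot.scan_pwm(w, result.pwm, bg, config.scan_p_threshold)
            if hit:
                fh.write(f"{hit.promoter_id}\t{hit.offset}\t{hit.score:.4f}\t{hit.pvalue:.3e}\n")
    obs, exp, p = mot.alu_enrichment_test(
        windows, genome.repeats, genome, config.alu_permutations,
        np.random.default_rng(config.seed)
    )
    with open(out / "alu_enrichment.json", "w") as fh:
        json.dump({"observed_mean": obs, "expected_mean": exp, "pvalue": p}, fh, indent=1)


def pwm_to_meme(pwm, name: str) -> str:
    """MEME minimal motif format."""
    lines = [
        "MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
        "Background letter frequencies", "A 0.25 C 0.25 G 0.25 T 0.25", "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= {max(pwm.site_count, 1)}",
    ]
    for row in pwm.probs:
        lines.append(" ".join(f"{v:.6f}" for v in row))
    lines.append("")
    return "\n".join(lines)


_STAGE_FUNCS = {
    "qc": _stage_qc,
    "tfe": _stage_tfe,
    "normalize": _stage_normalize,
    "annotate": _stage_annotate,
    "de": _stage_de,
    "cluster": _stage_cluster,
    "motifs": _stage_motifs,
}
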