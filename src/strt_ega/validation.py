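"""Simulation-based validation studies: parameter recovery on planted truth.

Each function runs one end-to-end study on synthetic data generated under
the study conditions (staged cells, per-division content halving, planted
activation/degradation/motifs/repeats) and returns the measured recovery
quantities. They are used by the test suite and by ``scripts/acceptance.py``.
"""
from __future__ import annotations

from collections import Counter
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from . import tfe as stfe
from .cluster import bootstrap_outliers, hcluster, masked_spearman
from .diffexp import DEParams, de_test
from .motifs import extract_promoter, alu_enrichment_test, zoops_em_discover
from .normalize import spikein_normalize
from .simulate import (
    DegradationModel,
    SimConfig,
    StageSpec,
    _sample_site,
    build_toy_genome,
    default_motif_pwm,
    simulate_de_counts,
    simulate_experiment,
)


def assemble_experiment(genome, tags, sheet, params: stfe.AssemblyParams | None = None):
    """Cluster tags per stage, merge, count and normalize (the qc->tfe->
    normalize front of the pipeline, in memory)."""
    params = params or stfe.AssemblyParams()
    stage_of = dict(zip(sheet["sample_id"], sheet["stage"]))
    protos = {
        st: stfe.cluster_tags([t for t in tags if stage_of[t.sample] == st], params, st)
        for st in sheet["stage"].unique()
    }
    tfes = stfe.merge_sample_types(protos)
    stfe.count_per_sample(tfes, tags)
    stfe.assign_peaks(tfes, tags)
    samples = list(sheet["sample_id"])
    counts = stfe.count_matrix(tfes, samples)
    spikes = (
        pd.Series(Counter(t.sample for t in tags if t.spike))
        .reindex(samples)
        .fillna(0)
        .astype(int)
    )
    stages = pd.Series(dict(zip(sheet["sample_id"], sheet["stage"])))
    em = spikein_normalize(counts, spikes, stages)
    return tfes, em


def tss_recovery(seed: int = 0) -> tuple[int, int]:
    """Planted-TSS recovery on a 20-gene, 2x12-cell jitter-free simulation.

    Returns (recovered, expected): over both sample types, the number of
    planted TSSs supported by >= 5 tags whose merged TFE peak equals the
    planted position exactly, and the number of such TSSs.
    """
    cfg = SimConfig(
        n_genes=20,
        stages=[StageSpec("oocyte", 12, 100_000), StageSpec("4cell", 12, 25_000)],
        ega_genes={"4cell": tuple(range(5))},
        seed=seed,
    )
    genome = build_toy_genome(cfg)
    tags, sheet, truth = simulate_experiment(genome, cfg)
    tfes, _ = assemble_experiment(genome, tags, sheet)
    peaks = {(t.contig, t.strand, t.peak) for t in tfes}
    stage_of = dict(zip(sheet["sample_id"], sheet["stage"]))
    recovered = expected = 0
    for stage in sheet["stage"].unique():
        at_pos = Counter(
            (t.contig, t.strand, t.pos)
            for t in tags
            if not t.spike and stage_of[t.sample] == stage
        )
        for tr in genome.transcripts:
            key = (tr.contig, tr.strand, tr.tss)
            if at_pos.get(key, 0) >= 5:
                expected += 1
                recovered += key in peaks
    return recovered, expected


def de_power_and_fdr(
    seed: int = 0, n_null_seeds: int = 10
) -> dict[str, float]:
    """Power on 30 planted 8-fold up-genes among 500 (n = 12 vs 12) and the
    false-call rate on pure-null companion runs."""
    params = DEParams(resamples=20, permutations=1000, divisions=1, seed=seed)
    counts, spikes, group, up = simulate_de_counts(
        500, n1=12, n2=12, n_up=30, fold=8.0, seed=seed
    )
    g2 = (group == "B").to_numpy()
    stats, q = de_test(counts, spikes, g2, params)
    called = set(counts.index[(q < params.q_threshold) & (stats > 0)])
    power = len(called & up) / len(up)

    null_fracs = []
    for k in range(n_null_seeds):
        c, sp, gr, _ = simulate_de_counts(500, n1=12, n2=12, n_up=0, seed=seed + 1 + k)
        p2 = DEParams(resamples=20, permutations=1000, divisions=1, seed=seed + 1 + k)
        _, qq = de_test(c, sp, (gr == "B").to_numpy(), p2)
        null_fracs.append(float((qq < p2.q_threshold).mean()))
    return {
        "power": power,
        "null_false_call_rate": float(np.mean(null_fracs)),
        "n_null_seeds": n_null_seeds,
    }


def division_correction(seed: int = 0) -> dict[str, float]:
    """Pure 4x dilution, no active degradation: down-call rates with the
    division correction (D = 4) and without (D = 1)."""
    counts, spikes, group, _ = simulate_de_counts(
        500, n1=12, n2=12, n_up=0, dilution=4.0, seed=seed
    )
    g2 = (group == "B").to_numpy()
    params = DEParams(resamples=20, permutations=1000, divisions=1, seed=seed)
    stat_c, q_c = de_test(counts, spikes, g2, params, scale_group2=4)
    stat_u, q_u = de_test(counts, spikes, g2, params, scale_group2=1)
    return {
        "down_rate_corrected": float(((q_c < 0.05) & (stat_c < 0)).mean()),
        "down_rate_uncorrected": float(((q_u < 0.05) & (stat_u < 0)).mean()),
    }


def motif_recovery(seed: int = 0) -> dict[str, float]:
    """ZOOPS EM on 60 windows, 40 carrying a planted 12-bp site: column-wise
    Pearson correlation of the fitted PWM with truth and EM monotonicity."""
    rng = np.random.default_rng(seed)
    pwm_true = default_motif_pwm(12)
    seqs = []
    for i in range(60):
        s = "".join(rng.choice(list("ACGT"), 200))
        if i < 40:
            site = _sample_site(pwm_true, rng)
            off = int(rng.integers(0, 189))
            s = s[:off] + site + s[off + 12:]
        seqs.append(s)
    res = zoops_em_discover(seqs, 12, rng=np.random.default_rng(seed))
    truth = pwm_true / pwm_true.sum(axis=1, keepdims=True)
    corr = float(
        np.mean([np.corrcoef(res.pwm.probs[i], truth[i])[0, 1] for i in range(12)])
    )
    diffs = np.diff(res.ll_trace)
    monotone = bool((diffs >= -1e-9 * abs(res.ll_trace[0])).all())
    planted_found = int((res.site_posteriors[:40] > 0.5).sum())
    return {
        "pwm_column_correlation": corr,
        "ll_monotone": monotone,
        "planted_sites_found": planted_found,
    }


def alu_enrichment(seed: int = 0, n_null_reps: int = 20) -> dict[str, float]:
    """Promoter repeat density 2.0 vs background 1.1 on 50 activated
    promoters: permutation p-value plus a null calibration run."""
    cfg = SimConfig(
        n_genes=300,
        ega_genes={"4cell": tuple(range(50))},
        promoter_repeat_density=2.0,
        background_repeat_density=1.1,
        stages=[StageSpec("oocyte", 2, 1000), StageSpec("4cell", 2, 1000)],
        seed=seed,
    )
    genome = build_toy_genome(cfg)
    tr = {t.id: t for t in genome.transcripts}
    windows = []
    for tid in genome.meta["activated"]:
        t = tr[tid]
        f = stfe.TFE(tid, t.contig, t.strand, t.tss, t.tss + 1)
        f.peak = t.tss
        windows.append(extract_promoter(f, genome))
    obs, exp, p = alu_enrichment_test(
        windows, genome.repeats, genome, 1000, np.random.default_rng(seed)
    )

    # null calibration: no planted promoter repeats, windows placed randomly
    cfg0 = SimConfig(
        n_genes=60, ega_genes={}, promoter_repeat_density=0.0,
        background_repeat_density=1.1,
        stages=[StageSpec("oocyte", 1, 100)], seed=seed + 1,
    )
    g0 = build_toy_genome(cfg0)
    clen = len(g0.contigs[0][1])
    rng = np.random.default_rng(seed + 2)
    null_ok = 0
    for _ in range(n_null_reps):
        wins = []
        for s in rng.integers(0, clen - 2600, size=50):
            f = stfe.TFE("W", "chr_sim", "+", int(s) + 2000, int(s) + 2001)
            f.peak = int(s) + 2000
            wins.append(extract_promoter(f, g0))
        null_ok += alu_enrichment_test(wins, g0.repeats, g0, 400, rng)[2] >= 0.05
    return {
        "observed_mean": float(obs),
        "expected_mean": float(exp),
        "pvalue": float(p),
        "null_calibration_fraction": null_ok / n_null_reps,
    }


def _rand_index(a: np.ndarray, b: np.ndarray) -> float:
    pairs = list(combinations(range(len(a)), 2))
    agree = sum((a[i] == a[j]) == (b[i] == b[j]) for i, j in pairs)
    return agree / len(pairs)


def stage_separation(seed: int = 0, n_seeds: int = 10) -> dict[str, float]:
    """Stage recovery by clustering (Rand index at k = 2) and planted
    mislabeled-cell detection by bootstrap outlier exclusion, over seeds."""
    rand_indices = []
    outlier_hits = 0
    for k in range(n_seeds):
        cfg = SimConfig(
            n_genes=40,
            stages=[StageSpec("oocyte", 12, 50_000), StageSpec("4cell", 12, 12_500)],
            ega_genes={"4cell": tuple(range(8))},
            seed=seed + k,
        )
        genome = build_toy_genome(cfg)
        tags, sheet, _ = simulate_experiment(genome, cfg)
        _, em = assemble_experiment(genome, tags, sheet)
        cm = masked_spearman(em.values, min_pairs=10)
        Z, _, _ = hcluster(cm)
        labels = sch.fcluster(Z, 2, criterion="maxclust")
        truth = (em.stages[cm.corr.columns] == "oocyte").astype(int).to_numpy()
        rand_indices.append(_rand_index(labels, truth))

        stages = em.stages.copy()
        planted = "4cell_00"
        stages[planted] = "oocyte"  # mislabel one 4-cell blastomere
        flags = bootstrap_outliers(
            em.values, stages, B=100, min_pairs=10, rng=np.random.default_rng(seed + k)
        )
        outlier_hits += bool(flags.loc[planted, "outlier"])
    return {
        "mean_rand_index": float(np.mean(rand_indices)),
        "outlier_detection_rate": outlier_hits / n_seeds,
        "n_seeds": n_seeds,
    }
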