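"""Synthetic-data generator: genome construction, experiment sampling,
maternal truncation and determinism."""
import numpy as np
import pytest

import strt_ega as se
from strt_ega.motifs import scan_pwm, PWM, extract_promoter
from strt_ega.simulate import (
    DegradationModel,
    SimConfig,
    StageSpec,
    _sample_site,
    build_toy_genome,
    simulate_experiment,
    truncate_maternal,
)
from strt_ega.tfe import TFE


def two_stage_cfg(**kw):
    defaults = dict(
        n_genes=20,
        stages=[StageSpec("oocyte", 4, 20_000), StageSpec("4cell", 4, 5_000)],
        ega_genes={"4cell": (0, 1, 2)},
        seed=3,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestBuildToyGenome:
    def test_minimal_single_coding_gene(self):
        cfg = SimConfig(n_genes=1, frac_noncoding=0.0, ega_genes={},
                        stages=[StageSpec("oocyte", 1, 100)], seed=0)
        g = build_toy_genome(cfg)
        assert len(g.transcripts) == 1
        assert g.transcripts[0].coding
        g.validate()

    def test_contig_too_short_raises(self):
        cfg = two_stage_cfg(contig_length=1000)
        with pytest.raises(ValueError, match="too short"):
            build_toy_genome(cfg)

    def test_determinism_byte_identical(self):
        cfg = two_stage_cfg()
        a, b = build_toy_genome(cfg), build_toy_genome(cfg)
        assert a.contigs == b.contigs
        assert a.repeats == b.repeats
        assert [(t.id, t.exons, t.cds) for t in a.transcripts] == [
            (t.id, t.exons, t.cds) for t in b.transcripts
        ]

    def test_planted_promoter_repeat_density(self):
        cfg = SimConfig(
            n_genes=60, ega_genes={"4cell": tuple(range(50))},
            promoter_repeat_density=2.0,
            stages=[StageSpec("oocyte", 1, 100), StageSpec("4cell", 1, 100)],
            seed=13,
        )
        g = build_toy_genome(cfg)
        counts = []
        windows = g.meta["promoter_windows"]
        planted = g.meta["promoter_repeats"]
        for tid in g.meta["activated"]:
            ws, we = windows[tid]
            counts.append(sum(1 for r in planted if r["transcript"] == tid))
        assert 1.7 <= np.mean(counts) <= 2.3

    def test_every_activated_promoter_carries_a_motif(self):
        cfg = two_stage_cfg()
        g = build_toy_genome(cfg)
        planted = {m["transcript"] for m in g.meta["motif_instances"]}
        assert planted == set(g.meta["activated"])

    def test_planted_motif_recoverable_by_scanning(self):
        """Scoring the true promoter windows with the true PWM finds a
        significant site at the planted offset."""
        from strt_ega.motifs import _discretize, _log_odds, encode, score_distribution_pvalue

        cfg = two_stage_cfg()
        g = build_toy_genome(cfg)
        pwm = PWM(cfg.pwm / cfg.pwm.sum(axis=1, keepdims=True))
        bg = np.full(4, 0.25)
        units = _discretize(_log_odds(pwm, bg), 0.01)
        tr = {t.id: t for t in g.transcripts}
        assert g.meta["motif_instances"]
        for inst in g.meta["motif_instances"]:
            t = tr[inst["transcript"]]
            tfe = TFE(t.id, t.contig, t.strand, t.tss, t.tss + 1)
            tfe.peak = t.tss
            w = extract_promoter(tfe, g)
            off = inst["window_offset"]
            # the oriented window carries the sampled site at the recorded offset
            assert w.seq[off : off + pwm.width] == inst["site"]
            obs = int(units[np.arange(pwm.width), encode(w.seq)[off : off + pwm.width]].sum())
            assert score_distribution_pvalue(pwm, bg, obs) < 1e-3


class TestTruncateMaternal:
    def test_fraction_zero_identity(self, rng):
        offsets = np.zeros(100, dtype=int)
        out = truncate_maternal(offsets, np.full(100, 500), 0.0, DegradationModel(), rng)
        assert (out == offsets).all()

    def test_fraction_one_constant_offset_clips_to_end(self, rng):
        model = DegradationModel(mean_offset=10_000, dist="constant")
        out = truncate_maternal(
            np.zeros(50, dtype=int), np.full(50, 400), 1.0, model, rng
        )
        assert (out == 399).all()

    def test_binomial_truncation_count(self, rng):
        out = truncate_maternal(
            np.zeros(10_000, dtype=int), np.full(10_000, 10**6), 0.5,
            DegradationModel(), rng,
        )
        assert abs((out > 0).sum() - 5000) <= 150

    def test_invalid_fraction(self, rng):
        with pytest.raises(ValueError):
            truncate_maternal(np.zeros(1, dtype=int), np.ones(1), 1.5, DegradationModel(), rng)


class TestSimulateExperiment:
    def test_zero_cells_empty(self):
        cfg = SimConfig(n_genes=3, stages=[StageSpec("oocyte", 0, 1000)], ega_genes={}, seed=0)
        g = build_toy_genome(cfg)
        tags, sheet, truth = simulate_experiment(g, cfg)
        assert tags == [] and len(sheet) == 0

    def test_spike_tags_binomial_expectation(self):
        cfg = SimConfig(
            n_genes=5, stages=[StageSpec("oocyte", 20, 1000)], ega_genes={},
            spike_molecules=1000, capture_efficiency=0.1, seed=4,
        )
        g = build_toy_genome(cfg)
        tags, sheet, _ = simulate_experiment(g, cfg)
        per_cell = {}
        for t in tags:
            if t.spike:
                per_cell[t.sample] = per_cell.get(t.sample, 0) + 1
        mean = np.mean([per_cell.get(s, 0) for s in sheet["sample_id"]])
        assert abs(mean - 100) <= 3 * np.sqrt(100 / 20)

    def test_dilution_ratio_between_stages(self):
        cfg = SimConfig(
            n_genes=10,
            stages=[StageSpec("oocyte", 8, 100_000), StageSpec("4cell", 8, 25_000)],
            ega_genes={}, degradation=DegradationModel(), seed=5,
        )
        g = build_toy_genome(cfg)
        tags, sheet, _ = simulate_experiment(g, cfg)
        stage_of = dict(zip(sheet["sample_id"], sheet["stage"]))
        ratios = {"oocyte": [], "4cell": []}
        for s in sheet["sample_id"]:
            gtags = sum(1 for t in tags if t.sample == s and not t.spike)
            stags = sum(1 for t in tags if t.sample == s and t.spike)
            ratios[stage_of[s]].append(gtags / stags)
        r = np.mean(ratios["oocyte"]) / np.mean(ratios["4cell"])
        assert 3.3 <= r <= 4.8

    def test_tags_bounded_by_budget_and_spikes_stage_independent(self):
        cfg = two_stage_cfg()
        g = build_toy_genome(cfg)
        tags, sheet, _ = simulate_experiment(g, cfg)
        budgets = {s.name: s.mrna_budget for s in cfg.stages}
        stage_of = dict(zip(sheet["sample_id"], sheet["stage"]))
        spikes = {"oocyte": [], "4cell": []}
        for s in sheet["sample_id"]:
            genomic = sum(1 for t in tags if t.sample == s and not t.spike)
            assert genomic <= budgets[stage_of[s]]
            spikes[stage_of[s]].append(sum(1 for t in tags if t.sample == s and t.spike))
        assert abs(np.mean(spikes["oocyte"]) - np.mean(spikes["4cell"])) < 15

    def test_zero_capture_warns_and_yields_no_genomic_tags(self):
        cfg = two_stage_cfg(capture_efficiency=0.0)
        g = build_toy_genome(cfg)
        with pytest.warns(UserWarning, match="capture"):
            tags, _, _ = simulate_experiment(g, cfg)
        assert not any(not t.spike for t in tags)

    def test_intact_tags_at_planted_tss(self):
        cfg = two_stage_cfg(degradation=DegradationModel())
        g = build_toy_genome(cfg)
        tags, _, truth = simulate_experiment(g, cfg)
        tss = set(truth.tss.values())
        assert all(t.pos in tss for t in tags if not t.spike)

    def test_determinism(self):
        cfg = two_stage_cfg()
        g = build_toy_genome(cfg)
        a = simulate_experiment(g, cfg)
        b = simulate_experiment(g, cfg)
        assert a[0] == b[0]
        assert a[1].equals(b[1])
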