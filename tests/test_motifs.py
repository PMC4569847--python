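"""Promoter extraction, PWM scanning with exact p-values, ZOOPS EM and Alu
overlap enrichment."""
import itertools

import numpy as np
import pytest

import strt_ega as se
from strt_ega.genome import GenomeModel, RepeatInterval, revcomp
from strt_ega.motifs import (
    PWM,
    _discretize,
    _log_odds,
    alu_enrichment_test,
    alu_overlap,
    encode,
    extract_promoter,
    scan_pwm,
    score_distribution_pvalue,
    zoops_em_discover,
)
from strt_ega.simulate import _sample_site, default_motif_pwm
from strt_ega.tfe import TFE


def peak_tfe(peak, strand="+", contig="c1"):
    t = TFE("FE1", contig, strand, peak, peak + 1)
    t.peak = peak
    return t


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 10_000))
    return GenomeModel(contigs=[("c1", seq)])


class TestExtractPromoter:
    def test_plus_strand_window(self, toy_genome):
        w = extract_promoter(peak_tfe(5000, "+"), toy_genome)
        assert (w.start, w.end, w.length) == (3000, 5500, 2500)
        assert w.seq == toy_genome.contig_seq("c1")[3000:5500]
        assert not w.clipped

    def test_minus_strand_window_revcomp(self, toy_genome):
        w = extract_promoter(peak_tfe(5000, "-"), toy_genome)
        assert (w.start, w.end) == (4501, 7001)
        assert w.seq == revcomp(toy_genome.contig_seq("c1")[4501:7001])

    def test_clipping_at_contig_start(self, toy_genome):
        w = extract_promoter(peak_tfe(1000, "+"), toy_genome)
        assert (w.start, w.end) == (0, 1500)
        assert w.clipped

    def test_orientation_mirror_symmetry(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 6000))
        g_fwd = GenomeModel(contigs=[("c1", seq)])
        g_rev = GenomeModel(contigs=[("c1", revcomp(seq))])
        peak = 3000
        w_plus = extract_promoter(peak_tfe(peak, "+"), g_fwd)
        w_minus = extract_promoter(peak_tfe(len(seq) - 1 - peak, "-"), g_rev)
        assert w_plus.seq == w_minus.seq

    def test_peak_outside_contig_errors(self, toy_genome):
        with pytest.raises(ValueError, match="outside contig"):
            extract_promoter(peak_tfe(50_000), toy_genome)


class TestPWM:
    def test_from_sites_rows_normalized(self):
        pwm = PWM.from_sites(["ACGT", "ACGT", "ACGA"])
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)
        assert (pwm.probs > 0).all()
        assert pwm.consensus() == "ACGT"

    def test_rejects_zero_entries(self):
        with pytest.raises(ValueError, match="positive"):
            PWM(np.array([[1.0, 0.0, 0.0, 0.0]]))


@pytest.fixture(scope="module")
def acgt_pwm():
    return PWM.from_sites(["ACGT"] * 100, pseudocount=0.01)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(42)
    pwm_true = default_motif_pwm(12)
    seqs = []
    for i in range(60):
        s = "".join(rng.choice(list("ACGT"), 200))
        if i < 40:
            site = _sample_site(pwm_true, rng)
            off = int(rng.integers(0, 189))
            s = s[:off] + site + s[off + 12:]
        seqs.append(s)
    return seqs, pwm_true


class TestScanPWM:
    def test_degenerate_pwm_finds_its_site(self, acgt_pwm):
        hit = scan_pwm("TTACGTTT", acgt_pwm, p_threshold=0.01)
        assert hit is not None and hit.offset == 2
        assert hit.pvalue == pytest.approx(0.25**4)  # only the exact match scores as high

    def test_no_hit_below_threshold(self, acgt_pwm):
        assert scan_pwm("T" * 50, acgt_pwm, p_threshold=1e-10) is None

    def test_window_shorter_than_motif(self, acgt_pwm):
        assert scan_pwm("AC", acgt_pwm) is None

    @pytest.mark.parametrize("width", [4, 6, 8])
    def test_pvalue_matches_exhaustive_enumeration(self, width, rng):
        """DP tail mass equals brute-force enumeration over all 4^W windows."""
        sites = ["".join(rng.choice(list("ACGT"), width)) for _ in range(20)]
        pwm = PWM.from_sites(sites, pseudocount=0.1)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        units = _discretize(_log_odds(pwm, bg), 0.01)
        idx = np.arange(width)
        for probe in [sites[0], "A" * width, "".join(rng.choice(list("ACGT"), width))]:
            obs = int(units[idx, encode(probe)].sum())
            dp = score_distribution_pvalue(pwm, bg, obs, 0.01)
            enum = sum(
                np.prod(bg[list(w)])
                for w in itertools.product(range(4), repeat=width)
                if units[idx, list(w)].sum() >= obs
            )
            assert dp == pytest.approx(float(enum), rel=1e-9)


class TestZoopsEM:
    def test_recovers_planted_motif(self, planted):
        seqs, pwm_true = planted
        res = zoops_em_discover(seqs, 12, rng=np.random.default_rng(0))
        truth = pwm_true / pwm_true.sum(axis=1, keepdims=True)
        corrs = [
            np.corrcoef(res.pwm.probs[i], truth[i])[0, 1] for i in range(12)
        ]
        assert np.mean(corrs) >= 0.8
        assert (res.site_posteriors[:40] > 0.5).sum() >= 35

    def test_loglik_nondecreasing(self, planted):
        seqs, _ = planted
        res = zoops_em_discover(seqs, 12, rng=np.random.default_rng(0))
        diffs = np.diff(res.ll_trace)
        assert (diffs >= -1e-9 * abs(res.ll_trace[0])).all()

    def test_planted_llr_exceeds_pure_random(self, planted):
        seqs, _ = planted
        rng = np.random.default_rng(5)
        random_seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(60)]
        res_planted = zoops_em_discover(seqs, 12)
        res_random = zoops_em_discover(random_seqs, 12)
        assert res_planted.llr_vs_background > 2 * res_random.llr_vs_background

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            zoops_em_discover([], 8)


class TestAluOverlap:
    def window(self, start, end, contig="c1"):
        from strt_ega.motifs import PromoterWindow

        return PromoterWindow("FE1", contig, start, end, "+", "A" * (end - start))

    def test_partial_and_contained_overlaps(self):
        reps = [RepeatInterval("c1", 3100, 3400, "+", "AluY"),
                RepeatInterval("c1", 5400, 5600, "+", "AluSx")]
        out = alu_overlap([self.window(3000, 5500)], reps)
        assert out[0].count == 2

    def test_half_open_boundary(self):
        reps = [RepeatInterval("c1", 5500, 5800, "+", "AluY")]
        assert alu_overlap([self.window(3000, 5500)], reps)[0].count == 0

    def test_matches_all_pairs_oracle(self, rng):
        reps = [
            RepeatInterval("c1", int(s), int(s + rng.integers(10, 400)), "+", "AluY")
            for s in rng.integers(0, 50_000, size=200)
        ]
        wins = [self.window(int(s), int(s + 2500)) for s in rng.integers(0, 48_000, size=40)]
        got = [o.count for o in alu_overlap(wins, reps)]
        expect = [
            sum(1 for r in reps if r.start < w.end and r.end > w.start) for w in wins
        ]
        assert got == expect


class TestAluEnrichment:
    def test_planted_density_detected(self):
        cfg = se.SimConfig(
            n_genes=300,
            ega_genes={"4cell": tuple(range(50))},
            stages=[se.StageSpec("oocyte", 2, 1000), se.StageSpec("4cell", 2, 1000)],
            seed=7,
        )
        genome = se.build_toy_genome(cfg)
        tr = {t.id: t for t in genome.transcripts}
        windows = [
            extract_promoter(peak_tfe(tr[tid].tss, tr[tid].strand, "chr_sim"), genome)
            for tid in genome.meta["activated"]
        ]
        obs, exp, p = alu_enrichment_test(
            windows, genome.repeats, genome, 1000, np.random.default_rng(1)
        )
        assert obs > exp
        assert p < 0.01

    def test_null_calibration(self):
        # uniform repeats, random windows: p should be roughly uniform
        cfg = se.SimConfig(
            n_genes=60, ega_genes={}, promoter_repeat_density=0.0,
            stages=[se.StageSpec("oocyte", 1, 100)], seed=8,
        )
        genome = se.build_toy_genome(cfg)
        clen = len(genome.contigs[0][1])
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(10):
            wins = [
                extract_promoter(peak_tfe(int(s) + 2000, "+", "chr_sim"), genome)
                for s in rng.integers(0, clen - 2600, size=50)
            ]
            pvals.append(alu_enrichment_test(wins, genome.repeats, genome, 200, rng)[2])
        assert sum(p >= 0.05 for p in pvals) >= 8

    def test_zero_permutations_errors(self, toy_genome):
        from strt_ega.motifs import PromoterWindow

        w = PromoterWindow("FE1", "c1", 0, 100, "+", "A" * 100)
        with pytest.raises(ValueError):
            alu_enrichment_test([w], [], toy_genome, n_perm=0)

    def test_empty_windows_error(self, toy_genome):
        with pytest.raises(ValueError, match="windows"):
            alu_enrichment_test([], [], toy_genome)
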