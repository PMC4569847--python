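"""Nine-way TFE annotation classes, proportions and stage tests."""
import numpy as np
import pandas as pd
import pytest

from strt_ega.annotate import (
    AnnotationClass,
    AnnotationIndex,
    class_proportions,
    classify_all,
    classify_tfe,
    proportion_stage_test,
)
from strt_ega.genome import TranscriptModel
from strt_ega.normalize import ExpressionMatrix
from strt_ega.tfe import TFE

C = AnnotationClass


@pytest.fixture
def coding_transcript():
    # + strand: exon1 [1000,1200) with 5'UTR [1000,1100), CDS 1100..2500,
    # 3'UTR [2500,2600); intron [1200,2000)
    return TranscriptModel("T1", "c1", "+", [(1000, 1200), (2000, 2600)], (1100, 2500))


def tfe(start, end, strand="+", contig="c1"):
    return TFE("FE1", contig, strand, start, end)


class TestClassifyTfe:
    def test_coding_5utr(self, coding_transcript):
        assert classify_tfe(tfe(1050, 1060), [coding_transcript]) is C.CODING_5UTR

    def test_coding_upstream_within_500(self, coding_transcript):
        assert classify_tfe(tfe(690, 700), [coding_transcript]) is C.CODING_UPSTREAM

    def test_beyond_upstream_window_unannotated(self, coding_transcript):
        assert classify_tfe(tfe(390, 400), [coding_transcript]) is C.UNANNOTATED

    def test_priority_5utr_beats_intron(self, coding_transcript):
        other = TranscriptModel("T2", "c1", "+", [(900, 950), (1800, 1900)], (900, 1900))
        # [1050,1060) is 5'UTR of T1 and intron of T2: 5'UTR wins
        assert classify_tfe(tfe(1050, 1060), [other, coding_transcript]) is C.CODING_5UTR

    def test_opposite_strand_overlap_is_no_overlap(self, coding_transcript):
        assert classify_tfe(tfe(1050, 1060, strand="-"), [coding_transcript]) is C.UNANNOTATED

    def test_cds_3utr_intron(self, coding_transcript):
        assert classify_tfe(tfe(1150, 1160), [coding_transcript]) is C.CODING_CDS
        assert classify_tfe(tfe(2550, 2560), [coding_transcript]) is C.CODING_3UTR
        assert classify_tfe(tfe(1500, 1510), [coding_transcript]) is C.INTRON

    def test_noncoding_classes(self):
        nc = TranscriptModel("N1", "c1", "-", [(100, 200), (300, 400)], None)
        # '-' strand: first exon in transcription order is [300,400)
        assert classify_tfe(tfe(350, 360, "-"), [nc]) is C.NONCODING_FIRST_EXON
        assert classify_tfe(tfe(150, 160, "-"), [nc]) is C.NONCODING_OTHER_EXON
        assert classify_tfe(tfe(450, 460, "-"), [nc]) is C.NONCODING_UPSTREAM


def brute_force_class(t, transcripts, upstream=500):
    """Per-base scan over the raw exon/CDS coordinates, independent of the
    interval-tree classifier."""
    bases = range(t.start, t.end)

    def overlaps(lo, hi):
        return any(lo <= b < hi for b in bases)

    hits = set()
    for tr in transcripts:
        if tr.strand != t.strand or tr.contig != t.contig:
            continue
        exonic = {b for s, e in tr.exons for b in range(s, e)}
        gene_lo, gene_hi = tr.exons[0][0], tr.exons[-1][1]
        if tr.strand == "+":
            upstream_iv = (gene_lo - upstream, gene_lo)
        else:
            upstream_iv = (gene_hi, gene_hi + upstream)
        if tr.cds is not None:
            cs, ce = tr.cds
            for b in bases:
                if b in exonic:
                    if tr.strand == "+":
                        if b < cs:
                            hits.add(C.CODING_5UTR)
                        elif b >= ce:
                            hits.add(C.CODING_3UTR)
                        else:
                            hits.add(C.CODING_CDS)
                    else:
                        if b >= ce:
                            hits.add(C.CODING_5UTR)
                        elif b < cs:
                            hits.add(C.CODING_3UTR)
                        else:
                            hits.add(C.CODING_CDS)
                elif gene_lo <= b < gene_hi:
                    hits.add(C.INTRON)
            if overlaps(*upstream_iv):
                hits.add(C.CODING_UPSTREAM)
        else:
            first = tr.exons[0] if tr.strand == "+" else tr.exons[-1]
            for b in bases:
                if first[0] <= b < first[1]:
                    hits.add(C.NONCODING_FIRST_EXON)
                elif b in exonic:
                    hits.add(C.NONCODING_OTHER_EXON)
                elif gene_lo <= b < gene_hi:
                    hits.add(C.INTRON)
            if overlaps(*upstream_iv):
                hits.add(C.NONCODING_UPSTREAM)
    for cls in C:
        if cls in hits:
            return cls
    return C.UNANNOTATED


def test_classifier_agrees_with_per_base_oracle(rng):
    """100% agreement with a brute-force per-base scan on 1,000 random TFEs."""
    transcripts = []
    pos = 0
    for i in range(30):
        pos += int(rng.integers(600, 1500))
        strand = "+" if rng.random() < 0.5 else "-"
        exons, cur = [], pos
        for _ in range(int(rng.integers(1, 4))):
            end = cur + int(rng.integers(50, 300))
            exons.append((cur, end))
            cur = end + int(rng.integers(50, 400))
        coding = rng.random() < 0.7
        cds = None
        if coding:
            lo, hi = exons[0][0], exons[-1][1]
            cs = int(rng.integers(lo, hi - 1))
            ce = int(rng.integers(cs + 1, hi + 1))
            covered = sum(max(0, min(e, ce) - max(s, cs)) for s, e in exons)
            cds = (cs, ce) if covered > 0 else None
        transcripts.append(TranscriptModel(f"T{i}", "c1", strand, exons, cds))
        pos = exons[-1][1]
    index = AnnotationIndex(transcripts)
    span = transcripts[-1].end + 1000
    for _ in range(1000):
        s = int(rng.integers(0, span))
        t = tfe(s, s + int(rng.integers(1, 120)), strand="+" if rng.random() < 0.5 else "-")
        got = index.classify(t.contig, t.start, t.end, t.strand)
        assert got is brute_force_class(t, transcripts)


class TestClassProportions:
    @staticmethod
    def em(values):
        df = pd.DataFrame(values)
        return ExpressionMatrix(
            df, pd.Series(1000, index=df.columns), pd.Series("x", index=df.columns)
        )

    def test_single_tfe_fraction_one(self):
        fr = class_proportions(self.em({"s1": [3.0]}), {0: C.CODING_CDS})
        assert fr.loc["s1", "coding_cds"] == 1.0

    def test_expression_weighted_fractions(self):
        fr = class_proportions(
            self.em({"s1": [3.0, 1.0]}), {0: C.CODING_5UTR, 1: C.INTRON}
        )
        assert fr.loc["s1", "coding_5utr"] == pytest.approx(0.75)
        assert fr.loc["s1", "intron"] == pytest.approx(0.25)

    def test_fractions_sum_to_one(self, rng):
        vals = pd.DataFrame(rng.random((20, 5)), columns=[f"s{i}" for i in range(5)])
        classes = {i: list(C)[i % 9] for i in range(20)}
        fr = class_proportions(self.em(vals), classes)
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)

    def test_all_zero_sample_flagged_nan(self):
        fr = class_proportions(
            self.em({"s1": [1.0, 0.0], "s2": [0.0, 0.0]}),
            {0: C.CODING_5UTR, 1: C.INTRON},
        )
        assert fr.loc["s2"].isna().all()

    def test_degradation_shifts_mass_into_gene_bodies(self):
        import strt_ega as se

        runs = {}
        for frac in (0.0, 0.5):
            cfg = se.SimConfig(
                n_genes=15,
                stages=[se.StageSpec("4cell", 6, 20_000)],
                ega_genes={},
                degradation=se.DegradationModel({"4cell": frac}),
                seed=5,
            )
            genome = se.build_toy_genome(cfg)
            tags, sheet, _ = se.simulate_experiment(genome, cfg)
            from collections import Counter

            from strt_ega import tfe as stfe

            protos = {"4cell": stfe.cluster_tags(tags, stfe.AssemblyParams(), "4cell")}
            tfes = stfe.merge_sample_types(protos)
            stfe.count_per_sample(tfes, tags)
            samples = list(sheet["sample_id"])
            counts = stfe.count_matrix(tfes, samples)
            spikes = pd.Series(Counter(t.sample for t in tags if t.spike)).reindex(samples)
            em = ExpressionMatrix(
                counts / 1.0, spikes, pd.Series("4cell", index=samples)
            )
            classes = classify_all(tfes, genome.transcripts)
            fr = class_proportions(em, classes)
            body = ["coding_cds", "coding_3utr", "noncoding_other_exon"]
            runs[frac] = fr[body].sum(axis=1).mean()
        assert runs[0.5] > runs[0.0] + 0.1


class TestProportionStageTest:
    def test_identical_distributions(self):
        fr = pd.DataFrame({"coding_upstream": [0.5] * 6, "coding_5utr": [0.1] * 6})
        stages = pd.Series(["a"] * 3 + ["b"] * 3, index=fr.index)
        assert proportion_stage_test(fr, stages, ("a", "b"), "coding_5prime") == 1.0

    def test_exact_extreme(self):
        fr = pd.DataFrame({"coding_upstream": [0.1, 0.2, 0.3, 0.7, 0.8, 0.9],
                           "coding_5utr": [0.0] * 6})
        stages = pd.Series(["a"] * 3 + ["b"] * 3, index=fr.index)
        assert proportion_stage_test(fr, stages, ("a", "b"), "coding_5prime") == pytest.approx(0.1)
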