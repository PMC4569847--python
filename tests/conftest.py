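import numpy as np
import pandas as pd
import pytest

import strt_ega as se
from strt_ega import tfe as stfe


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_experiment():
    """20-gene, two-stage (12+12 cells) simulated experiment with truth."""
    cfg = se.SimConfig(
        n_genes=20,
        stages=[se.StageSpec("oocyte", 12, 100_000), se.StageSpec("4cell", 12, 25_000)],
        ega_genes={"4cell": tuple(range(5))},
        seed=2,
    )
    genome = se.build_toy_genome(cfg)
    tags, sheet, truth = se.simulate_experiment(genome, cfg)
    return cfg, genome, tags, sheet, truth


@pytest.fixture(scope="session")
def assembled(small_experiment):
    """TFE set + counts + expression matrix assembled from the simulation."""
    from collections import Counter

    cfg, genome, tags, sheet, truth = small_experiment
    stage_of = dict(zip(sheet["sample_id"], sheet["stage"]))
    params = stfe.AssemblyParams()
    protos = {
        st: stfe.cluster_tags([t for t in tags if stage_of[t.sample] == st], params, st)
        for st in sheet["stage"].unique()
    }
    tfes = stfe.merge_sample_types(protos)
    stfe.count_per_sample(tfes, tags)
    stfe.assign_peaks(tfes, tags)
    samples = list(sheet["sample_id"])
    counts = stfe.count_matrix(tfes, samples)
    spike = (
        pd.Series(Counter(t.sample for t in tags if t.spike))
        .reindex(samples)
        .fillna(0)
        .astype(int)
    )
    stages = pd.Series(dict(zip(sheet["sample_id"], sheet["stage"])))
    em = se.spikein_normalize(counts, spike, stages)
    return tfes, counts, em


def make_tags(positions, contig="c1", strand="+", sample="s1"):
    return [stfe.AlignedTag(contig, p, strand, sample) for p in positions]
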