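import numpy as np
import pandas as pd
import pytest

from phagetime.io import GeneFeature, SampleMeta, TimeCourseCounts


def make_counts(matrix, times, gene_meta=None, normalized=False):
    """Build a TimeCourseCounts from a dict {gene_id: row} and time points."""
    sample_ids = [f"t{int(t):02d}" for t in times]
    from phagetime.io import DEFAULT_PHASE_GROUPING, phase_of

    samples = [
        SampleMeta(sid, float(t), phase_of(float(t), DEFAULT_PHASE_GROUPING))
        for sid, t in zip(sample_ids, times)
    ]
    values = pd.DataFrame.from_dict(matrix, orient="index", columns=sample_ids)
    features = {}
    pos = 1
    for gid in matrix:
        organism, strand = ("host", "+")
        if gene_meta and gid in gene_meta:
            organism, strand = gene_meta[gid]
        features[gid] = GeneFeature(gid, organism, pos, pos + 99, strand,
                                    organism=organism)
        pos += 200
    return TimeCourseCounts(
        values=values, samples=samples, features=features, normalized=normalized
    )


FULL_TIMES = (0, 2, 5, 10, 15, 21, 28, 35, 42, 49)


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated dataset (seed 11, coverage on), shared read-only."""
    from phagetime.simulate import SimConfig, simulate_infection

    cfg = SimConfig(seed=11)
    features, counts, intervals, truth = simulate_infection(cfg)
    return cfg, features, counts, intervals, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
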