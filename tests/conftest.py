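import numpy as np
import pandas as pd
import pytest

from omicscreen.rnaseq import CountMatrix
from omicscreen.simulate import SimConfig, simulate_rnaseq_counts


def planted_effects(n_genes: int, n_effects: int, magnitude: float, seed: int):
    """Random signed effects of fixed magnitude on a random gene subset."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_genes, n_effects, replace=False)
    return tuple(
        (f"gene_{i:05d}", float(magnitude * rng.choice([-1.0, 1.0]))) for i in idx
    )


@pytest.fixture(scope="session")
def default_rna_fixture():
    """The default planted RNA fixture: 2,000 genes, 20 planted |log2FC| >= 2,
    8 replicates per condition, moderate dispersion."""
    effects = planted_effects(2000, 20, 2.0, seed=42)
    cfg = SimConfig(n_genes=2000, n_replicates=8, seed=7, effect_table=effects)
    cm, truth = simulate_rnaseq_counts(cfg)
    return cm, truth, {f for f, _ in effects}


@pytest.fixture()
def tiny_count_matrix():
    """Hand-sized 4-gene x 6-sample matrix (2 replicates per condition)."""
    genes = ["g1", "g2", "g3", "g4"]
    cols = ["control_1", "control_2", "wildtype_1", "wildtype_2", "mutant_1", "mutant_2"]
    counts = pd.DataFrame(
        [
            [10, 12, 100, 110, 25, 30],
            [50, 55, 200, 190, 210, 205],
            [5, 6, 40, 42, 160, 150],
            [80, 85, 90, 88, 92, 95],
        ],
        index=pd.Index(genes, name="feature_id"),
        columns=cols,
    )
    samples = pd.DataFrame(
        {
            "condition": ["control"] * 2 + ["wildtype"] * 2 + ["mutant"] * 2,
            "replicate": [1, 2, 1, 2, 1, 2],
        },
        index=pd.Index(cols, name="sample_id"),
    )
    lengths = pd.Series([1000, 2000, 500, 1500], index=counts.index)
    return CountMatrix(counts=counts, lengths=lengths, samples=samples)
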