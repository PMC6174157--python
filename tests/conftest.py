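import numpy as np
import pandas as pd
import pytest

from mirtfnet.quantify import CountMatrix
from mirtfnet.synthetic import SimulationConfig, generate_cohort

# A desk-scale cohort shared across test modules (generation is deterministic).
TINY_PARAMS = dict(
    n_genes=120,
    n_tfs=15,
    n_mirnas=40,
    planted_up_mirnas=10,
    planted_down_mirnas=2,
    hub_site_mirnas=8,
    targets_per_mirna=3,
    target_pool_genes=10,
    utr_length_range=(150, 400),
    library_size_range=(100_000, 150_000),
    n_go_terms=12,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(rng_seed=7, **TINY_PARAMS)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    genes, mirnas, mrna_cm, mirna_cm, truth = generate_cohort(tiny_config)
    return {
        "config": tiny_config,
        "genes": genes,
        "mirnas": mirnas,
        "mrna": mrna_cm,
        "mirna": mirna_cm,
        "truth": truth,
    }


def make_count_matrix(
    counts: np.ndarray,
    feature_ids=None,
    n_pairs=None,
    lengths=None,
    total_clean=None,
    mapped=None,
) -> CountMatrix:
    """Paired-design CountMatrix around a raw array (tumor, normal, ...)."""
    counts = np.asarray(counts)
    n_features, n_samples = counts.shape
    assert n_samples % 2 == 0
    n_pairs = n_pairs or n_samples // 2
    feature_ids = feature_ids or [f"F{i}" for i in range(n_features)]
    sample_ids, pair_ids, conditions = [], [], []
    for p in range(n_pairs):
        sample_ids += [f"P{p + 1}_T", f"P{p + 1}_N"]
        pair_ids += [f"P{p + 1}", f"P{p + 1}"]
        conditions += ["tumor", "normal"]
    colsums = counts.sum(axis=0)
    samples = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "condition": conditions,
            "total_clean_reads": total_clean if total_clean is not None else colsums * 2,
            "uniquely_mapped_reads": mapped if mapped is not None else colsums,
        },
        index=sample_ids,
    )
    fl = pd.Series(lengths, index=feature_ids) if lengths is not None else None
    return CountMatrix(
        pd.DataFrame(counts, index=feature_ids, columns=sample_ids),
        samples,
        feature_lengths=fl,
    )
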