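import numpy as np
import pandas as pd
import pytest

from sbcln import (
    CascadeConfig,
    SyntheticConfig,
    labels_series,
    normalize_single_cohort,
    select_housekeeping,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small 3-entity cohort: raw counts, normalized matrix, labels, config."""
    cfg = SyntheticConfig(
        entities=("CLL/SLL", "FL", "MZL"),
        samples_per_entity=10,
        n_controls=12,
        markers_per_entity=4,
        n_background_genes=20,
        n_housekeeping_genes=4,
        seed=11,
    )
    matrix, anns = simulate_cohort(cfg)
    hk = select_housekeeping(matrix, matrix.housekeeping_candidates)
    norm = normalize_single_cohort(matrix, hk)
    return {
        "config": cfg,
        "matrix": matrix,
        "annotations": anns,
        "norm": norm,
        "labels": labels_series(anns),
        "candidates": cfg.panel().candidate_genes,
    }


@pytest.fixture(scope="session")
def small_cascade_config():
    """Light forests for unit tests: fewer trees, fixed k matching the planted
    4-marker blocks of the small cohort."""
    return CascadeConfig(n_estimators=50, markers_per_entity=4, seed=5)


@pytest.fixture(scope="session")
def small_model(small_sim, small_cascade_config):
    from sbcln import fit_cascade

    return fit_cascade(
        small_sim["norm"], small_sim["labels"], small_sim["candidates"], small_cascade_config
    )


def make_norm_df(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)
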