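import numpy as np
import pandas as pd
import pytest

from scmodules import ExpressionMatrix
from scmodules.synthetic_data import SyntheticConfig, generate_single_cell_dataset


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 cells with zeros, sub-floor and ordinary values."""
    df = pd.DataFrame(
        {
            "c1": [0.4, 0.0, 5.0],
            "c2": [0.1, 0.8, 5.0],
            "c3": [0.05, 0.0, 5.0],
            "c4": [2.0, 0.0, 5.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic single-cell dataset, shared across tests."""
    cfg = SyntheticConfig()
    m, truth = generate_single_cell_dataset(cfg, 12345)
    return cfg, m, truth


def f1_score(found: set, truth: set) -> float:
    tp = len(found & truth)
    fp = len(found - truth)
    fn = len(truth - found)
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def run_cleaning(m, cells=None):
    """Cleaning chain shared by recovery tests: all-zero -> simple -> ubiquitous."""
    from scmodules.cleaning import (
        drop_all_zero_genes,
        simple_pattern_filter,
        ubiquitous_filter,
    )
    from scmodules.expression_io import floor_fpkm, log2_fold_change

    cells = cells or m.sample_ids
    m, _ = drop_all_zero_genes(m, cells)
    removed, _ = simple_pattern_filter(floor_fpkm(m), cells)
    m = m.subset_genes([g for g in m.gene_ids if g not in removed])
    fc = log2_fold_change(floor_fpkm(m), cells)
    removed, _ = ubiquitous_filter(fc, cells)
    fc = fc.subset_genes([g for g in fc.gene_ids if g not in removed])
    sd = fc.values.std(axis=1)
    return fc.subset_genes(list(sd.index[sd > 1e-12]))


def discover_module(fc, r_seed=0.9, r_expand=0.75, min_size=5):
    from scmodules.module_discovery import (
        expand_module,
        find_seed_groups,
        pairwise_correlation,
    )

    corr = pairwise_correlation(fc)
    groups = find_seed_groups(corr, r_seed=r_seed, min_size=min_size)
    if not groups:
        return None
    return expand_module(set().union(*groups), corr, r_expand=r_expand)
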