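"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mixbiome as mb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_table() -> mb.AbundanceTable:
    """16 samples x 8 taxa relative table with a binary group label."""
    t = mb.synthesize_abundance_table(
        n_samples=16, n_taxa=8, zero_fraction_range=(0.1, 0.5),
        taxonomy_breadth=4, seed=42,
    )
    rng = np.random.default_rng(7)
    t.metadata["grp"] = rng.integers(0, 2, size=16)
    return t


@pytest.fixture(scope="session")
def counts_table() -> mb.AbundanceTable:
    """A small counts-mode table with known zeros."""
    data = pd.DataFrame(
        [[2.0, 2.0, 4.0, 0.0],
         [1.0, 0.0, 3.0, 0.0],
         [0.0, 5.0, 5.0, 0.0],
         [4.0, 4.0, 2.0, 2.0]],
        index=[f"s{i}" for i in range(4)],
        columns=[f"t{j}" for j in range(4)],
    )
    return mb.AbundanceTable(data=data, mode="counts")


@pytest.fixture(scope="session")
def signal_study():
    """A mid-sized table with planted signal taxa and a drawn outcome.

    Scaled for unit tests: 150 samples x 60 taxa, 6 signal taxa.
    """
    t = mb.synthesize_abundance_table(n_samples=150, n_taxa=60, seed=11)
    design = mb.assign_signal_taxa(
        t, n_strong=1, n_medium=2, n_weak=3, seed=12, calibrate_prevalence=0.20
    )
    y = mb.simulate_test_variable(t, design, seed=13)
    t.metadata["test"] = y
    ranked = mb.rank_table(t, levels=4)
    return t, ranked, design


@pytest.fixture(scope="session")
def ranked_small(small_table) -> mb.RankedMatrix:
    return mb.rank_table(small_table, levels=4)
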