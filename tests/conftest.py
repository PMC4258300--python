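"""Shared fixtures: small synthetic designs and toy matrices."""

import numpy as np
import pandas as pd
import pytest

from coexmod import (
    ExpressionMatrix,
    PlantedModuleSpec,
    SimulationConfig,
    default_config,
    simulate_cohorts,
    simulate_gene_sets,
)


def make_matrix(values, gene_ids=None, sample_ids=None, phenotype=None):
    """Build an ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    sample_ids = sample_ids or [f"s{j}" for j in range(s)]
    if phenotype is None:
        phenotype = [1] * (s // 2) + [0] * (s - s // 2)
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        pd.Series(phenotype, index=sample_ids),
    )


def small_config(seed=0, **overrides) -> SimulationConfig:
    """A scaled-down two-term design for fast unit tests."""
    base = dict(
        n_genes=400,
        n_train_case=30,
        n_train_ctrl=20,
        n_test_case=25,
        n_test_ctrl=15,
        n_go_terms=2,
        go_size_range=(40, 60),
        planted_modules=(
            PlantedModuleSpec("T01", size=20, loading=0.9, case_shift=1.2),
            PlantedModuleSpec("T02", size=15, loading=0.9, case_shift=1.2,
                              preserved=False),
        ),
        missing_rate=0.0,
        n_outliers=0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_design():
    """One realization of the full default design (shared, read-only)."""
    cfg = default_config(seed=11)
    train, test, truth = simulate_cohorts(cfg)
    sets = simulate_gene_sets(truth, cfg)
    return cfg, train, test, truth, sets


@pytest.fixture(scope="session")
def small_cohorts():
    cfg = small_config(seed=5)
    train, test, truth = simulate_cohorts(cfg)
    return cfg, train, test, truth
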