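import dataclasses

import numpy as np
import pandas as pd
import pytest

import rrtempo as rt


@pytest.fixture(scope="session")
def small_config() -> rt.SimulationConfig:
    """Desk-scale planted study: 300 genes, 8 subjects/group."""
    return rt.SimulationConfig(n_genes=300, seed=1)


@pytest.fixture(scope="session")
def small_study(small_config):
    matrix, truth = rt.generate_expression(small_config)
    collection = rt.generate_gene_sets(small_config, truth)
    return matrix, truth, collection


@pytest.fixture(scope="session")
def null_study():
    """No planted effects at all: beta = gamma = 0."""
    config = rt.SimulationConfig(n_genes=400, n_subjects_per_group=8,
                                 beta=0.0, gamma=0.0, seed=9)
    matrix, truth = rt.generate_expression(config)
    return config, matrix, truth


def fixture_pipeline_config(seed: int = 11) -> rt.AnalysisConfig:
    """The bundled end-to-end fixture: 500 genes, 8 subjects/group,
    six planted pattern modules plus six decoy sets, reduced permutation
    counts for a quick full run."""
    return rt.AnalysisConfig(
        simulation=rt.SimulationConfig(seed=0),
        n_perm_de=200, n_perm_gsea=100, som_epochs=15, seed=seed,
    )
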