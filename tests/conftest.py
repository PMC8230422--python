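import numpy as np
import pandas as pd
import pytest

from cdcsig import (
    ExpressionMatrix,
    GeneSet,
    SimBulkConfig,
    SimPanelConfig,
    SimSingleCellConfig,
    simulate_bulk_compendium,
    simulate_cell_line_panel,
    simulate_single_cell,
)


@pytest.fixture(scope="session")
def bulk_compendium():
    """Four small tumorA/tumorB/normal datasets with planted DE structure."""
    cfg = SimBulkConfig(
        n_genes=2000,
        datasets=[
            (f"d{i}", {"tumorA": 10, "tumorB": 10, "normal": 10})
            for i in range(1, 5)
        ],
        planted_specific_genes=30,
        planted_shared_genes=100,
        planted_down_genes=50,
        specific_log2_fc=2.0,
        shared_log2_fc=2.0,
        down_log2_fc=2.0,
        batch_sd=0.5,
        noise_sd=0.5,
        seed=11,
    )
    return simulate_bulk_compendium(cfg)


@pytest.fixture(scope="session")
def single_cell():
    cfg = SimSingleCellConfig(
        n_genes=2000,
        cell_types=(("typeA", 100, 50, 2.0), ("typeB", 100, 50, 2.0),
                    ("typeC", 100, 50, 2.0)),
        dropout_rate=0.3,
        seed=7,
    )
    return simulate_single_cell(cfg)


@pytest.fixture(scope="session")
def signature31():
    return GeneSet("tumor_signature", tuple(f"sg{i:02d}" for i in range(31)),
                   direction="up")


@pytest.fixture(scope="session")
def drug_panel(signature31):
    cfg = SimPanelConfig(
        n_cell_lines=200, n_compounds=100, n_active_compounds=20,
        slope=-0.5, auc_noise_sd=0.05, seed=5,
    )
    return simulate_cell_line_panel(cfg, signature31)


@pytest.fixture()
def tiny_matrix():
    """5-gene, 1-sample matrix behind the hand-worked scoring example."""
    return ExpressionMatrix(
        pd.DataFrame({"s1": [1.0, 3.0, 2.0, 5.0, 4.0]},
                     index=["g1", "g2", "g3", "g4", "g5"])
    )
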