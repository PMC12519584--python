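from io import StringIO

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from plaquedyn import CommunityTable, ModuleSpec, ScenarioConfig, simulate_recovery_series, simulate_tree


@pytest.fixture
def four_tip_tree() -> TreeNode:
    """Symmetric 4-tip tree with unit branch lengths."""
    return TreeNode.read(StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def tiny_table() -> CommunityTable:
    df = pd.DataFrame(
        {"S1": [5, 0, 5], "S2": [2, 2, 6]},
        index=["taxon_1", "taxon_2", "taxon_3"],
    )
    return CommunityTable(df)


def small_scenario(seed=1, noise_sd=0.3, drivers=(), n_subjects=12, n_taxa=60):
    """Compact recovery scenario with one module per stage."""
    cfg = ScenarioConfig(
        n_subjects=n_subjects,
        n_taxa=n_taxa,
        seed=seed,
        noise_sd=noise_sd,
        module_spec=[
            ModuleSpec("black", 8, "early", 2.0, baseline_scale=0.3),
            ModuleSpec("red", 8, "middle", 2.0),
            ModuleSpec("blue", 14, "late", 0.7),
        ],
        driver_spec=list(drivers),
    )
    tree = simulate_tree(cfg.n_taxa, seed=seed)
    table, metadata, truth = simulate_recovery_series(cfg, tree)
    return cfg, tree, table, metadata, truth


@pytest.fixture
def recovery_small():
    return small_scenario()
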