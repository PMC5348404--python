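import numpy as np
import pandas as pd
import pytest

from bindgap import chemlib, exprstats, synthgen


def make_dataset(values_by_stage, group="g", transform="log2"):
    """Build a tiny one-gene ExpressionDataset from {stage: [values]}."""
    stages, vals = [], []
    for stage, xs in values_by_stage.items():
        stages += [stage] * len(xs)
        vals += list(xs)
    sample_ids = [f"s{i}" for i in range(len(vals))]
    meta = pd.DataFrame(
        {"stage": stages, "group": [group] * len(vals)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame([vals], index=pd.Index(["G"], name="gene_id"), columns=sample_ids)
    return exprstats.ExpressionDataset(values, meta, transform=transform)


@pytest.fixture
def toy_dataset():
    """Three stages of two samples: {1,2}, {3,4}, {5,6} -> F = 16, df (2, 3)."""
    return make_dataset({"a": [1, 2], "b": [3, 4], "c": [5, 6]})


@pytest.fixture(scope="session")
def small_library():
    """Fixed-seed synthetic library (reference + 25 analogs + 15 decoys)."""
    table = synthgen.gen_library(synthgen.LibrarySimConfig(n_analogs=25, n_decoys=15, seed=11))
    compounds = chemlib.make_library(table[["id", "smiles"]].itertuples(index=False))
    return table, compounds


@pytest.fixture(scope="session")
def planted_screen():
    """Standard planted docking screen: 100 compounds, 5 specific, gap 3."""
    config = synthgen.DockSimConfig(seed=23)
    truth, poses = synthgen.gen_poses(config)
    return config, truth, poses
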