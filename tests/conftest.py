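import numpy as np
import pandas as pd
import pytest

from maap.io import FeatureMatrix, InteractionRecord, InteractionTable
from maap.synthetic import SynthConfig, generate


@pytest.fixture
def tiny_table() -> InteractionTable:
    """Six records, two receptors, one ligand shared across receptors."""
    rows = [
        ("L1", "CCO", "R1", 0, [10.0]),
        ("L2", "CCN", "R1", 1, [12.0]),
        ("L3", "c1ccccc1O", "R1", 2, []),
        ("L1", "CCO", "R2", 1, [5.0]),
        ("L4", "c1ccncc1", "R2", 0, [7.0]),
        ("L5", "CCCC", "R2", 2, [3.0]),
    ]
    return InteractionTable([
        InteractionRecord(ligand_id=l, smiles=s, receptor_id=r,
                          action_class=c, ki_values_nM=k)
        for l, s, r, c, k in rows
    ])


@pytest.fixture
def small_matrix() -> FeatureMatrix:
    return FeatureMatrix(
        row_keys=[("L1", "R1"), ("L2", "R1"), ("L3", "R2")],
        column_names=["D1", "D2", "E1", "E2"],
        column_roles=["descriptor", "descriptor", "embedding", "embedding"],
        values=np.array([[1.0, 5.0, 0.1, 2.0],
                         [1.0, 6.0, 0.2, 2.0],
                         [1.0, 7.0, 0.3, 2.0]]),
    )


def small_synth_config(seed: int = 1, **overrides) -> SynthConfig:
    """Reduced-size generator config for fast model-fitting tests."""
    base = dict(n_receptors=8, n_ligands=120, n_pairs=360, n_descriptors=24,
                n_constant_descriptors=4, n_embedding_dims=16,
                n_informative_descriptors=4, n_informative_embedding_dims=6,
                seed=seed)
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def small_synth_dataset():
    """One shared small synthetic dataset (seed 1) for model-level tests."""
    return generate(small_synth_config(seed=1))
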