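import numpy as np
import pytest

import cellfuse as cf


@pytest.fixture(scope="session")
def atlas8():
    """Default study-condition atlas: 8 types in 4 subclasses, 2,000 genes."""
    return cf.default_atlas(seed=11)


@pytest.fixture(scope="session")
def trio(atlas8):
    """Small three-modality dataset trio for fast integration tests."""
    specs = cf.default_dataset_specs(seed=11, n_cells=400)
    return [cf.simulate_dataset(atlas8, s) for s in specs]


@pytest.fixture(scope="session")
def rna_small(atlas8):
    spec = cf.DatasetSpec(
        "rna_cell", platform="10x", n_cells=300, depth=5000.0,
        dispersion=10.0, coupling=1.0, seed=5, name="rna",
    )
    return cf.simulate_dataset(atlas8, spec)


@pytest.fixture(scope="session")
def rna_norm(rna_small):
    return cf.normalize(rna_small)


def true_types(datasets) -> np.ndarray:
    return np.concatenate([d.cells["true_type"].to_numpy() for d in datasets])
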