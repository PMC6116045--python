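import numpy as np
import pytest

from dbpstack import pipeline, stacking
from dbpstack import synthetic_data as sd

SMALL_GRIDS = {kind: stacking.small_grid(kind) for kind in stacking.CLASSIFIER_KINDS}


def dataset_matrices(ds, params=None):
    """Extract all four blocks and return (matrices, labels, ids)."""
    blocks, labels, _ = pipeline.extract_dataset(
        ds.records, ds.pssms, ds.ss, params or pipeline.FeatureParams()
    )
    matrices, ids = pipeline.blocks_to_matrices(blocks)
    y = np.array([labels[rid] for rid in ids])
    return matrices, y, ids


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 labeled synthetic proteins with a strong planted PSSM signal."""
    return sd.generate(
        sd.SyntheticConfig(
            n_pos=6, n_neg=6, length_range=(50, 70), pssm_effect=3.0, seed=7
        )
    )


@pytest.fixture(scope="session")
def tiny_tree(tiny_dataset, tmp_path_factory):
    root = tmp_path_factory.mktemp("fixture_tree")
    sd.write_fixture_tree(tiny_dataset, root)
    return root


@pytest.fixture(scope="session")
def planted_matrices():
    """Feature matrices for 32 proteins with a planted PSSM signal."""
    ds = sd.generate(
        sd.SyntheticConfig(
            n_pos=16, n_neg=16, length_range=(50, 80), pssm_effect=3.0, seed=11
        )
    )
    return dataset_matrices(ds)


@pytest.fixture
def svm_specs():
    return stacking.specs_for_family("svm", grids=SMALL_GRIDS)
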