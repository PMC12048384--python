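import numpy as np
import pytest

from cbbgwo import (PipelineConfig, SyntheticConfig, encode_dataset,
                    generate, preprocess)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-motif dataset: 3 classes x 10, short sequences."""
    config = SyntheticConfig(n_classes=3, n_per_class=10,
                             length_range=(36, 54), motifs_per_class=2,
                             insertion_rate=3.0, seed=42)
    records, truth = generate(config)
    clean, _ = preprocess(records)
    matrix = encode_dataset(clean)
    return matrix, truth, records


@pytest.fixture()
def tiny_pipeline_config():
    """Pipeline settings scaled for the tiny dataset (fast, deterministic)."""
    return PipelineConfig(master_seed=7, n_clusters=4, kmeans_restarts=3,
                          pop_size=5, n_iterations=8, cv_folds=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
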