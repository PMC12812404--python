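import pytest

import lorentzvae as lv
from lorentzvae.synthetic import SyntheticSpec, generate_rna


@pytest.fixture(scope="session")
def small_rna():
    """300 cells x 120 genes, 4 well-separated clusters."""
    spec = SyntheticSpec(n_cells=300, n_features=120, n_clusters=4,
                         hierarchy_depth=2, de_strength=1.2, seed=11)
    return generate_rna(spec)


@pytest.fixture(scope="session")
def small_processed(small_rna):
    X, _ = small_rna
    return lv.preprocess(X)


@pytest.fixture(scope="session")
def trained_small(small_processed):
    """A briefly trained default-architecture model on the small fixture."""
    cfg = lv.ModelConfig(seed=3, epochs=40, early_stopping=False)
    model, trace = lv.fit(small_processed, config=cfg)
    return model, trace
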