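import numpy as np
import pytest

from ordgeom import DesignSpec, EffectSpec, generate_counts, generate_metadata, generate_tree


@pytest.fixture(scope="session")
def small_design():
    """Compact microcosm design: 3 soils x 2 treatments x 2 reps x 5 days."""
    return DesignSpec(replicates=2, n_features=80, library_size=20_000, seed=11)


@pytest.fixture(scope="session")
def small_effects():
    return EffectSpec(inoculant_feature_id="OTU0001")


@pytest.fixture(scope="session")
def small_table(small_design, small_effects):
    return generate_counts(small_design, small_effects)


@pytest.fixture(scope="session")
def small_metadata(small_design):
    return generate_metadata(small_design)


@pytest.fixture(scope="session")
def small_tree(small_design):
    return generate_tree(small_design.n_features, seed=small_design.seed)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
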