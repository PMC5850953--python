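import numpy as np
import pytest

import phylocnn as pc


@pytest.fixture(scope="session")
def small_fixture():
    """Shared 16-feature fixture: tree, composition table, class stats."""
    return pc.random_fixture(42, p=16, n_per_class=40, alpha=2.0)


@pytest.fixture(scope="session")
def small_coords(small_fixture):
    tree, table, _ = small_fixture
    dm = pc.patristic_matrix(tree)
    return pc.classical_mds(dm).reorder(table.feature_labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
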