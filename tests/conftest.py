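import numpy as np
import pytest
from hypothesis import settings

# property tests must replay identically across environments
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tabbench.datatable import Table
from tabbench.fixtures import TableConfig, gen_app_bundle, gen_table


@pytest.fixture
def expr_table() -> Table:
    """100 rows x (id + 10 log-normal numeric columns), seeded."""
    return gen_table(TableConfig(n_rows=100, n_columns=10, seed=0))


@pytest.fixture
def mixed_table() -> Table:
    """Small table with one numeric and one text column."""
    return Table.from_dict(
        {"gene_name": ["a", "b", "c"], "score": [1.0, 2.0, 3.0]}
    )


@pytest.fixture
def app_dir(tmp_path):
    """Directory holding the three shipped app bundles."""
    bundle_dir = tmp_path / "apps"
    for name in ("simpleplot", "correlation", "fold_change_labeler"):
        gen_app_bundle(name, bundle_dir)
    return bundle_dir


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
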