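import numpy as np
import pandas as pd
import pytest

from methylprofiler.io import BETA, MethylationMatrix
from methylprofiler.synthetic import default_simulation, write_fixture_bundle


def make_matrix(values, sample_ids=None, cpg_ids=None, scale=BETA):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(1, n + 1)]
    cpg_ids = cpg_ids or [f"cg{j:08d}" for j in range(1, p + 1)]
    return MethylationMatrix(
        pd.DataFrame(values, index=sample_ids, columns=cpg_ids), scale
    )


@pytest.fixture
def small_beta_matrix():
    rng = np.random.default_rng(7)
    return make_matrix(rng.uniform(0.05, 0.95, size=(4, 6)))


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A complete synthetic CSV bundle plus its generating simulation."""
    sim = default_simulation(seed=11)
    directory = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(sim, directory)
    return sim, paths
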