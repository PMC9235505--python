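import numpy as np
import pytest

from makl import feature_sets, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_fixture():
    """A small labelled dataset with 6 sets of 10 genes, 2 informative.

    Sized for fast unit tests; the full-size default fixture is reserved
    for the acceptance suite.
    """
    spec = synthetic.SyntheticSpec(
        N=120, d=60, P=6, genes_per_set=10, k_informative=2, seed=11
    )
    dataset, sets, truth = synthetic.generate(spec)
    resolved = feature_sets.resolve(sets, dataset.gene_names)
    return dataset, resolved, truth


@pytest.fixture(scope="session")
def default_fixture():
    """The package's standard synthetic study (500 x 500, 20 sets, 3 informative)."""
    spec = synthetic.SyntheticSpec()
    dataset, sets, truth = synthetic.generate(spec)
    return dataset, sets, truth


@pytest.fixture
def gmt_file(tmp_path):
    def _write(lines, name="sets.gmt"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
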