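import numpy as np
import pytest

from splicedesign.oracle import generate_dataset, sample_oracle


@pytest.fixture(scope="session")
def oracle_spec():
    return sample_oracle(seed=5, n_tissues=3)


@pytest.fixture(scope="session")
def small_dataset(oracle_spec):
    """A small synthetic bundle shared by unit tests (60 events)."""
    return generate_dataset(oracle_spec, n_events=60, seed=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fa"
    path.write_text(">chrA\n" + "ACGT" * 500 + "\n>chrB\n"
                    + "GGCCAATT" * 300 + "\n")
    return path
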