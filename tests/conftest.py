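import numpy as np
import pytest

from phenotier import PhenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n_strains, n_resources, p=0.5, prefix=("s", "r")):
    values = (rng.random((n_strains, n_resources)) < p).astype(np.int8)
    return PhenotypeMatrix(
        tuple(f"{prefix[0]}{i}" for i in range(n_strains)),
        tuple(f"{prefix[1]}{j}" for j in range(n_resources)),
        values,
    )


@pytest.fixture
def random_matrix_factory(rng):
    def factory(n_strains, n_resources, p=0.5):
        return random_matrix(rng, n_strains, n_resources, p)

    return factory


def write_csv(path, text):
    path.write_text(text, encoding="utf-8")
    return path
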