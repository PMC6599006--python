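import numpy as np
import pytest

from idrpep.mj_energy import ContactEnergyMatrix, load_default_matrix, residue_averages


@pytest.fixture(scope="session")
def mj_matrix():
    return load_default_matrix()


@pytest.fixture(scope="session")
def mj_avgs(mj_matrix):
    return residue_averages(mj_matrix)


@pytest.fixture()
def toy_matrix():
    """2-letter matrix [[0, 3], [3, 0]]: E(1,2)=+1.5, E(1,1)=E(2,2)=-1.5."""
    return ContactEnergyMatrix(("1", "2"), np.array([[0.0, 3.0], [3.0, 0.0]]), "toy")


def random_symmetric_matrix(rng, alphabet):
    """Random symmetric contact matrix over the given alphabet."""
    n = len(alphabet)
    raw = rng.normal(0.0, 2.0, size=(n, n))
    return ContactEnergyMatrix(tuple(alphabet), (raw + raw.T) / 2.0, "random")


def write_matrix_file(path, alphabet, energies):
    lines = [" ".join(alphabet)]
    for code, row in zip(alphabet, energies):
        lines.append(code + " " + " ".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path
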