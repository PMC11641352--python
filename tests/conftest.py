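import numpy as np
import pytest

from tgvscreen import Fingerprint, gen_fingerprint_library


def make_fp(bits, length: int = 166, scheme: str = "maccs") -> Fingerprint:
    """Fingerprint with exactly the given bit indices set."""
    vec = np.zeros(length, dtype=bool)
    vec[list(bits)] = True
    return Fingerprint(bits=vec, scheme=scheme)


@pytest.fixture(scope="session")
def planted_library():
    """The planted 6×20 MACCS library used by the clustering checks."""
    return gen_fingerprint_library(k=6, m=20, bits=166, flip_prob=0.05, seed=0)


@pytest.fixture
def smi_file(tmp_path):
    def write(content: str, name: str = "lib.smi"):
        path = tmp_path / name
        path.write_text(content)
        return path

    return write
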