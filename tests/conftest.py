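import numpy as np
import pytest

from prbind.formats import PWM, parse_transfac
from prbind.pipeline import default_matrix_path


@pytest.fixture(scope="session")
def pre_library() -> list[PWM]:
    return parse_transfac(default_matrix_path())


@pytest.fixture(scope="session")
def pr01(pre_library) -> PWM:
    return next(p for p in pre_library if p.matrix_id == "V$PR_01")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
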