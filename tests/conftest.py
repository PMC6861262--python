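import numpy as np
import pytest

from swarmdx import CaseSet, DiagnosisSet


@pytest.fixture
def small_cases() -> CaseSet:
    """Four cases, two per class."""
    return CaseSet(("a", "b", "c", "d"), (0, 0, 1, 1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_diag(values, case_ids=("a", "b", "c", "d"), source="s", kind="reader"):
    return DiagnosisSet(source, kind, dict(zip(case_ids, values)))


@pytest.fixture
def random_study(rng):
    """A 30-case set with one random diagnosis source."""
    n = 30
    labels = rng.integers(0, 2, size=n)
    labels[0], labels[1] = 0, 1  # both classes always present
    ids = tuple(f"c{i}" for i in range(n))
    cases = CaseSet(ids, tuple(int(l) for l in labels))
    diag = DiagnosisSet("rand", "reader", dict(zip(ids, rng.random(n))))
    return cases, diag
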