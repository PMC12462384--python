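import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cppkit._tables import ALPHABET
from cppkit.matrix import FeatureMatrix
from cppkit.seqio import LabeledDataset, Peptide

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_AA = np.array(list(ALPHABET))


def random_peptide(rng: np.random.Generator, min_len: int = 3, max_len: int = 30) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(_AA, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    return LabeledDataset(
        [
            Peptide("p1", "KRKRKRKL", 1),
            Peptide("p2", "RRKKHLLG", 1),
            Peptide("p3", "DEDEDEGS", 0),
            Peptide("p4", "EEDDGSTA", 0),
        ]
    )


def planted_matrix(
    n_per_class: int = 100,
    n_noise: int = 50,
    sigma: float = 0.05,
    seed: int = 7,
) -> FeatureMatrix:
    """Labeled matrix with one feature equal to the label plus tiny noise and
    ``n_noise`` pure-noise features."""
    rng = np.random.default_rng(seed)
    labels = np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    signal = labels + rng.normal(0, sigma, size=labels.size)
    noise = rng.normal(0, 1, size=(labels.size, n_noise))
    values = np.column_stack([signal, noise])
    names = ["signal"] + [f"noise_{j:03d}" for j in range(n_noise)]
    ids = [f"row_{i:04d}" for i in range(labels.size)]
    return FeatureMatrix(ids=ids, names=names, values=values, labels=labels)
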