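import numpy as np
import pytest

from rankfuse.containers import OmicsMatrix, Signature, SurvivalTable


@pytest.fixture
def toy_matrix() -> OmicsMatrix:
    return OmicsMatrix(
        layer_name="toy",
        feature_ids=["f1", "f2", "f3"],
        subject_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture
def random_matrix() -> OmicsMatrix:
    rng = np.random.default_rng(11)
    return OmicsMatrix(
        layer_name="rand",
        feature_ids=[f"f{i}" for i in range(10)],
        subject_ids=[f"s{j}" for j in range(4)],
        values=rng.uniform(0.5, 10.0, size=(10, 4)),
    )


def make_signature(features, subject="s", layer="L", side="top") -> Signature:
    return Signature(subject_id=subject, layer_name=layer, side=side, feature_ids=list(features))


@pytest.fixture
def signature_factory():
    return make_signature


def random_signature_pair(rng, k: int, alphabet: int):
    """Two equal-length signatures over a shared alphabet (may overlap)."""
    assert alphabet >= k
    a = rng.choice(alphabet, size=k, replace=False)
    b = rng.choice(alphabet, size=k, replace=False)
    return [f"f{i}" for i in a], [f"f{i}" for i in b]


@pytest.fixture
def survival_60() -> SurvivalTable:
    rng = np.random.default_rng(5)
    return SurvivalTable(
        subject_ids=[f"s{i}" for i in range(60)],
        time=rng.exponential(200.0, 60) + 0.5,
        event=rng.integers(0, 2, 60),
    )
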