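import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pepconv.network import PeptideConvNet
from pepconv.synth import MotifSpec, generate_allele_dataset

STRONG_SEED = 20260928


@pytest.fixture(scope="session")
def strong_dataset():
    """The reference synthetic allele: n=2000, strong anchor motif, no label noise."""
    return generate_allele_dataset(MotifSpec(), n=2000, seed=STRONG_SEED)


@pytest.fixture(scope="session")
def strong_split(strong_dataset):
    """Deterministic 80/20 train/test split of the reference allele."""
    peps = strong_dataset.peptides
    labels = np.asarray(strong_dataset.labels)
    rng = np.random.default_rng(STRONG_SEED)
    idx = rng.permutation(len(peps))
    n_tr = int(0.8 * len(peps))
    tr, te = idx[:n_tr], idx[n_tr:]
    return (
        [peps[i] for i in tr], labels[tr],
        [peps[i] for i in te], labels[te],
    )


@pytest.fixture(scope="session")
def strong_model(strong_split):
    """Faithful-preset network fitted on the reference training split.

    Session-scoped: several tests probe the same fitted model.
    """
    X_tr, y_tr, _, _ = strong_split
    return PeptideConvNet(random_state=STRONG_SEED).fit(X_tr, y_tr)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
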