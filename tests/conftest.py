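import numpy as np
import pytest

from trustauc import (
    AUCMarginClassifier,
    SyntheticSpec,
    generate_synthetic_dataset,
)

# Study conditions reused across tests: a strongly-signaled ("separable")
# imbalanced dataset at desk scale. Signal is 5x the noise sd, so a linear
# read-out of blob intensity already separates the classes.
SEPARABLE = dict(signal_amplitude=0.75, noise_sd=0.15, image_side=32)


@pytest.fixture(scope="session")
def separable_ds(tmp_path_factory):
    spec = SyntheticSpec(
        n_neg=80, n_pos=40, seed=7, test_fraction=0.25, **SEPARABLE
    )
    return generate_synthetic_dataset(spec, tmp_path_factory.mktemp("separable"))


@pytest.fixture(scope="session")
def trained_clf(separable_ds):
    """An AUC-margin classifier fine-tuned on the separable fixture."""
    train = separable_ds.subset("train")
    clf = AUCMarginClassifier(
        loss="auc_margin", epochs=25, lr=0.1, batch_size=32, seed=0
    )
    return clf.fit(train.load(), train.labels())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
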