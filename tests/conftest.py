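import numpy as np
import pytest

import scintigrade as sg


@pytest.fixture(scope="session")
def noiseless_config():
    """Whole-body phantom config with all stochastic extras disabled."""
    return sg.PhantomConfig(noise_model="none", hotspot_rate=0.0,
                            metastasis_count=0, seed=7)


@pytest.fixture(scope="session")
def small_preprocessed_set():
    """Twelve preprocessed 128x128 phantom images (3 per grade), noise on."""
    studies = sg.generate_dataset(12, (0.25, 0.25, 0.25, 0.25), seed=5,
                                  metastasis_rate=0.25)
    return sg.preprocess_studies(studies)


def make_blob_images(n, n_classes, size=32, seed=0):
    """Cheap separable stand-in images: a central blob whose intensity
    encodes the class, plus noise. Used where full phantoms would be
    needlessly slow."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % n_classes
    X = rng.normal(0.0, 0.1, size=(n, size, size))
    r = size // 4
    for i, c in enumerate(y):
        X[i, r : 3 * r, r : 3 * r] += (c + 1) / n_classes
    return X, y
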