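import numpy as np
import pytest

from pathobrain.config import PipelineConfig
from pathobrain.synthetic import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def balanced_phantoms():
    """60 balanced phantoms at the default (separable) lesion contrast."""
    spec = PhantomSpec(n_images=60, fraction_pathological=0.5, seed=0)
    images, labels = generate_dataset(spec)
    return images, labels


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(seed=0)


@pytest.fixture(scope="session")
def phantom_features(balanced_phantoms, default_config):
    from pathobrain.pipeline import features_from_images

    images, labels = balanced_phantoms
    return features_from_images(images, default_config), labels


def principal_angle_deg(A: np.ndarray, B: np.ndarray) -> float:
    """Largest canonical angle (degrees) between the column spans of A and B."""
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return float(np.degrees(np.arccos(np.clip(s.min(), -1.0, 1.0))))
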