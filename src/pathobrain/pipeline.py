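"""End-to-end orchestration of the detection cascade.

Thin glue between the stage modules: preprocess a directory of slices
into the wavelet feature matrix, fit PPCA + ensemble on labelled
features, and score new images.  The CLI wraps these functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from pathobrain import ensemble as ens_mod
from pathobrain import ppca as ppca_mod
from pathobrain.config import PipelineConfig
from pathobrain.preprocessing import WienerSpec, load_image, wiener_filter
from pathobrain.synthetic import load_dataset
from pathobrain.wavelet import extract_features


def preprocess_image(img: np.ndarray, config: PipelineConfig) -> np.ndarray:
    if config.denoise:
        spec = WienerSpec(mode=config.wiener_mode, window=config.wiener_window)
        img = wiener_filter(img, spec)
    return img


def features_from_images(
    images: Sequence[np.ndarray], config: PipelineConfig
) -> np.ndarray:
    """Wiener-denoise then extract the level-3 LL feature vector per image."""
    rows = [
        extract_features(preprocess_image(img, config), config.wavelet_name, config.levels)
        for img in images
    ]
    return np.vstack(rows)


def features_from_directory(
    indir: Union[str, Path], config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load a class-layout dataset directory and extract features."""
    images, labels, names = load_dataset(indir)
    return features_from_images(images, config), labels, names


@dataclass
class FittedCascade:
    ppca: ppca_mod.PPCAModel
    ensemble: ens_mod.SubspaceEnsemble
    config: PipelineConfig


def train(X: np.ndarray, y: Sequence, config: PipelineConfig) -> FittedCascade:
    """Fit PPCA on the feature matrix, then the ensemble on the scores."""
    config.validate()
    model = ppca_mod.fit_ppca(
        X, k=config.ppca_k, tol=config.ppca_tol,
        max_iter=config.ppca_max_iter, seed=config.seed,
    )
    Z = ppca_mod.transform(model, X)
    ens = ens_mod.fit_ensemble(
        Z, y, n_members=config.n_members, subspace_dim=config.subspace_dim,
        K=config.K, seed=config.seed, tie_rule=config.tie_rule,
    )
    return FittedCascade(ppca=model, ensemble=ens, config=config)


def predict_features(cascade: FittedCascade, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and pathological vote fractions for a feature matrix."""
    Z = ppca_mod.transform(cascade.ppca, X)
    labels = ens_mod.predict(cascade.ensemble, Z)
    frac = ens_mod.vote_fraction(cascade.ensemble, Z)
    return labels, frac


def predict_images(
    paths: Sequence[Union[str, Path]], cascade: FittedCascade
) -> tuple[np.ndarray, np.ndarray]:
    config = cascade.config
    images = [
        preprocess_image(load_image(p, resize=config.resize), config) for p in paths
    ]
    X = np.vstack(
        [extract_features(img, config.wavelet_name, config.levels) for img in images]
    )
    return predict_features(cascade, X)


def save_cascade(cascade: FittedCascade, prefix: Union[str, Path]) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ppca_mod.save_model(cascade.ppca, prefix.with_suffix(".ppca.npz"))
    ens_mod.save_ensemble(cascade.ensemble, prefix.with_suffix(".ensemble.npz"))
    cascade.config.to_yaml(prefix.with_suffix(".config.yaml"))


def load_cascade(prefix: Union[str, Path]) -> FittedCascade:
    prefix = Path(prefix)
    return FittedCascade(
        ppca=ppca_mod.load_model(prefix.with_suffix(".ppca.npz")),
        ensemble=ens_mod.load_ensemble(prefix.with_suffix(".ensemble.npz")),
        config=PipelineConfig.from_yaml(prefix.with_suffix(".config.yaml")),
    )
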