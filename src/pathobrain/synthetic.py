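"""Synthetic 256x256 brain-slice phantoms with controllable pathology.

Each phantom is an elliptical "brain" mask with a smooth radial
intensity profile, band-limited texture (Gaussian-smoothed white
noise), and additive pixel noise.  Pathological phantoms additionally
carry a configurable number of hyperintense Gaussian blobs — lesion
stand-ins bright on a T2-like background — at random in-mask
positions.  Class separation is governed entirely by
``lesion_contrast``; at zero contrast the two classes are
exchangeable in distribution.

The default pathology is diffuse and multifocal: 25 broad foci (sigma
= radius/2 = 24 px) at 0.15 amplitude, emulating diseases with a heavy
load of overlapping hyperintense regions (confluent multiple-sclerosis
plaques, widespread metastases, tumour plus edema).  The aggregate
lesion field then carries a consistent class signature that global
subband features can learn; sparse small blobs at random positions
would instead add pure within-class variance, which distance-based
classifiers cannot separate.

The generator emulates the pathological-heavy class skew of curated
atlas collections (default 85% pathological) and writes the same
directory layout the loader consumes: class-named subdirectories of
PNGs plus a labels CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image
from scipy import ndimage

PATHOLOGICAL = "pathological"
NORMAL = "normal"

SIZE = 256
# semi-axes of the elliptical brain mask, in pixels
_SEMI_AXES = (108.0, 88.0)


@dataclass
class PhantomSpec:
    """Study conditions for one generated dataset."""

    n_images: int = 90
    fraction_pathological: float = 0.85
    lesion_count: int = 25
    lesion_radius: float = 48.0
    lesion_contrast: float = 0.15
    noise_sigma: float = 0.05
    texture_scale: float = 0.06
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not 0.0 <= self.fraction_pathological <= 1.0:
            raise ValueError("fraction_pathological must lie in [0, 1]")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be >= 0")
        if self.lesion_radius <= 0:
            raise ValueError("lesion_radius must be positive")
        if self.lesion_radius >= min(_SEMI_AXES):
            raise ValueError(
                f"lesion_radius={self.lesion_radius} does not fit inside the "
                f"brain mask (semi-axes {_SEMI_AXES})"
            )
        if self.lesion_contrast < 0 or self.noise_sigma < 0 or self.texture_scale < 0:
            raise ValueError("contrast, noise and texture amplitudes must be >= 0")
        return self

    @property
    def n_pathological(self) -> int:
        # half-up rounding: round(90 * 0.85) = 77
        return int(np.floor(self.n_images * self.fraction_pathological + 0.5))


def _mask_and_base() -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:SIZE, 0:SIZE]
    cy = cx = (SIZE - 1) / 2.0
    r2 = ((yy - cy) / _SEMI_AXES[0]) ** 2 + ((xx - cx) / _SEMI_AXES[1]) ** 2
    mask = r2 <= 1.0
    base = np.where(mask, 0.35 + 0.3 * (1.0 - r2), 0.02)
    return mask, base


def _one_phantom(rng: np.random.Generator, spec: PhantomSpec, pathological: bool) -> np.ndarray:
    mask, img = _mask_and_base()
    if spec.texture_scale > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal((SIZE, SIZE)), sigma=3.0)
        tex /= max(tex.std(), 1e-12)
        img = img + spec.texture_scale * tex * mask
    if pathological and spec.lesion_count > 0:
        yy, xx = np.mgrid[0:SIZE, 0:SIZE]
        # lesion centres drawn uniformly inside a margin-eroded mask
        cy = cx = (SIZE - 1) / 2.0
        margin = spec.lesion_radius
        ok = (
            ((yy - cy) / (_SEMI_AXES[0] - margin)) ** 2
            + ((xx - cx) / (_SEMI_AXES[1] - margin)) ** 2
        ) <= 1.0
        centres = np.flatnonzero(ok)
        picks = rng.choice(centres, size=spec.lesion_count, replace=False)
        sigma = spec.lesion_radius / 2.0
        for flat in picks:
            ly, lx = divmod(int(flat), SIZE)
            blob = np.exp(-(((yy - ly) ** 2 + (xx - lx) ** 2) / (2.0 * sigma**2)))
            img = img + spec.lesion_contrast * blob
    if spec.noise_sigma > 0:
        img = img + spec.noise_sigma * rng.standard_normal((SIZE, SIZE))
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: PhantomSpec) -> tuple[list[np.ndarray], np.ndarray]:
    """Generate labelled phantoms, fully reproducible from ``spec.seed``.

    Pathological images come first; label counts follow the half-up
    rounding of n_images * fraction_pathological.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_path = spec.n_pathological
    labels = np.array([PATHOLOGICAL] * n_path + [NORMAL] * (spec.n_images - n_path))
    images = [_one_phantom(rng, spec, lab == PATHOLOGICAL) for lab in labels]
    return images, labels


def save_dataset(
    images: list[np.ndarray], labels: np.ndarray, outdir: Union[str, Path]
) -> Path:
    """Write 8-bit PNGs into class-named subdirectories plus labels.csv."""
    outdir = Path(outdir)
    for cls in (PATHOLOGICAL, NORMAL):
        (outdir / cls).mkdir(parents=True, exist_ok=True)
    rows = []
    counters = {PATHOLOGICAL: 0, NORMAL: 0}
    for img, lab in zip(images, labels):
        name = f"{lab}_{counters[lab]:04d}.png"
        counters[lab] += 1
        arr = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(outdir / lab / name)
        rows.append((f"{lab}/{name}", lab))
    with open(outdir / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("filename", "label"))
        w.writerows(rows)
    return outdir


def load_dataset(indir: Union[str, Path]) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Read back a saved dataset: (images in [0,1], labels, filenames)."""
    from pathobrain.preprocessing import load_image

    indir = Path(indir)
    labels_path = indir / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"no labels.csv under {indir}")
    images, labels, names = [], [], []
    with open(labels_path, newline="") as fh:
        for row in csv.DictReader(fh):
            images.append(load_image(indir / row["filename"]))
            labels.append(row["label"])
            names.append(row["filename"])
    return images, np.asarray(labels), names
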