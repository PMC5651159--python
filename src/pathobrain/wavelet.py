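"""Separable multilevel 2D discrete wavelet transform with periodized boundaries.

The 1D analysis step is a circular (periodized) convolution with the
low/high-pass taps followed by downsampling by two:

    cA[k] = sum_m lo[m] * x[(2k + L/2 - m) mod N]
    cD[k] = sum_m hi[m] * x[(2k + L/2 - m) mod N]

so every level halves each dimension exactly, regardless of filter
length.  A three-level decomposition of a 256x256 slice therefore
carries 10 subbands, the deepest approximation (LL) being 32x32 = 1024
coefficients — the primary feature vector of the detection cascade.

Subband naming: the first letter is the filter applied along axis 0
(image rows as the leading dimension), the second along axis 1; LH is
low-pass along axis 0 and high-pass along axis 1.

Supported families (all with orthonormal analysis taps): haar, db2,
coif1, plus sym1 / bior1.1 / rbio1.1 whose order-1 members coincide
numerically with Haar.  Synthesis is the exact adjoint of the analysis
operator, which for these banks is the inverse, so reconstruction is
perfect to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

_SQRT2 = np.sqrt(2.0)
_SQRT3 = np.sqrt(3.0)
_SQRT7 = np.sqrt(7.0)

# Scaling (synthesis low-pass) coefficients, unit l2 norm.
_SCALING_COEFFS = {
    "haar": np.array([1.0, 1.0]) / _SQRT2,
    "db2": np.array([1 + _SQRT3, 3 + _SQRT3, 3 - _SQRT3, 1 - _SQRT3]) / (4 * _SQRT2),
    "coif1": np.array(
        [1 - _SQRT7, 5 + _SQRT7, 14 + 2 * _SQRT7, 14 - 2 * _SQRT7, 1 - _SQRT7, -3 + _SQRT7]
    ) * (_SQRT2 / 32),
}
# order-1 symlet and (reverse) biorthogonal banks share the Haar taps
_ALIASES = {"sym1": "haar", "bior1.1": "haar", "rbio1.1": "haar"}
#: families whose taps form an orthogonal bank by construction
_ORTHOGONAL = {"haar", "db2", "coif1", "sym1"}

FAMILIES = ("haar", "db2", "coif1", "sym1", "bior1.1", "rbio1.1")


@dataclass(frozen=True)
class WaveletFilterBank:
    """Analysis/synthesis FIR taps of one wavelet family."""

    name: str
    dec_lo: np.ndarray
    dec_hi: np.ndarray
    rec_lo: np.ndarray
    rec_hi: np.ndarray
    orthogonal: bool

    def __len__(self) -> int:
        return len(self.dec_lo)


def wavelet_bank(name: str) -> WaveletFilterBank:
    """Build the filter bank for a named family (see FAMILIES)."""
    key = _ALIASES.get(name, name)
    if key not in _SCALING_COEFFS:
        raise ValueError(f"unknown wavelet family {name!r}; choose from {FAMILIES}")
    h = _SCALING_COEFFS[key]
    k = np.arange(len(h))
    dec_lo = h[::-1].copy()
    dec_hi = ((-1.0) ** (k + 1)) * h  # quadrature mirror of the scaling taps
    rec_lo = h.copy()
    rec_hi = dec_hi[::-1].copy()
    return WaveletFilterBank(
        name=name,
        dec_lo=dec_lo,
        dec_hi=dec_hi,
        rec_lo=rec_lo,
        rec_hi=rec_hi,
        orthogonal=name in _ORTHOGONAL,
    )


def _as_bank(bank: Union[str, WaveletFilterBank]) -> WaveletFilterBank:
    return wavelet_bank(bank) if isinstance(bank, str) else bank


def _analysis_gather(n: int, L: int) -> np.ndarray:
    # index matrix: row k lists the signal samples hit by output k
    return (2 * np.arange(n // 2)[:, None] + L // 2 - np.arange(L)[None, :]) % n


def _dwt_axis(x: np.ndarray, bank: WaveletFilterBank, axis: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.moveaxis(np.asarray(x, dtype=np.float64), axis, -1)
    n = x.shape[-1]
    L = len(bank)
    if n % 2:
        raise ValueError(f"signal length {n} along axis {axis} must be even")
    if n < L:
        raise ValueError(f"signal length {n} shorter than filter support {L}")
    idx = _analysis_gather(n, L)
    g = x[..., idx]
    a = g @ bank.dec_lo
    d = g @ bank.dec_hi
    return np.moveaxis(a, -1, axis), np.moveaxis(d, -1, axis)


def _idwt_axis(a: np.ndarray, d: np.ndarray, bank: WaveletFilterBank, axis: int) -> np.ndarray:
    a = np.moveaxis(np.asarray(a, dtype=np.float64), axis, -1)
    d = np.moveaxis(np.asarray(d, dtype=np.float64), axis, -1)
    if a.shape != d.shape:
        raise ValueError("approximation and detail shapes differ")
    half = a.shape[-1]
    n = 2 * half
    L = len(bank)
    idx = _analysis_gather(n, L)
    out = np.zeros(a.shape[:-1] + (n,), dtype=np.float64)
    # adjoint of the gather-and-dot analysis step (scatter-add per tap)
    for m in range(L):
        np.add.at(out, (..., idx[:, m]), a * bank.dec_lo[m] + d * bank.dec_hi[m])
    return np.moveaxis(out, -1, axis)


def dwt1d(
    signal: Sequence[float], bank: Union[str, WaveletFilterBank]
) -> tuple[np.ndarray, np.ndarray]:
    """One analysis level of the periodized 1D DWT.

    Returns (approximation, detail) coefficient arrays, each of length
    n/2.  Odd-length signals are rejected.
    """
    bank = _as_bank(bank)
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("dwt1d expects a 1D signal")
    return _dwt_axis(x, bank, 0)


def idwt1d(
    approx: Sequence[float], detail: Sequence[float], bank: Union[str, WaveletFilterBank]
) -> np.ndarray:
    """Invert one level of dwt1d (exact for the supported banks)."""
    return _idwt_axis(np.asarray(approx), np.asarray(detail), _as_bank(bank), 0)


def dwt2(
    img: np.ndarray, bank: Union[str, WaveletFilterBank]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One level of the separable 2D DWT: returns (LL, LH, HL, HH)."""
    bank = _as_bank(bank)
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("dwt2 expects a 2D image")
    lo0, hi0 = _dwt_axis(img, bank, 0)
    ll, lh = _dwt_axis(lo0, bank, 1)
    hl, hh = _dwt_axis(hi0, bank, 1)
    return ll, lh, hl, hh


def idwt2(
    ll: np.ndarray,
    lh: np.ndarray,
    hl: np.ndarray,
    hh: np.ndarray,
    bank: Union[str, WaveletFilterBank],
) -> np.ndarray:
    """Invert one level of dwt2."""
    bank = _as_bank(bank)
    lo0 = _idwt_axis(ll, lh, bank, 1)
    hi0 = _idwt_axis(hl, hh, bank, 1)
    return _idwt_axis(lo0, hi0, bank, 0)


@dataclass
class DecompositionResult:
    """Multilevel subband pyramid.

    ``details[j]`` holds the (LH, HL, HH) triple produced at level j+1;
    ``approx`` is the deepest LL subband.  A 3-level result carries
    1 + 3*3 = 10 subbands.
    """

    levels: int
    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]

    @property
    def shapes(self) -> list[tuple[int, int]]:
        return [d[0].shape for d in self.details] + [self.approx.shape]

    @property
    def n_subbands(self) -> int:
        return 1 + 3 * self.levels

    def energy(self) -> float:
        total = float(np.sum(self.approx**2))
        for lh, hl, hh in self.details:
            total += float(np.sum(lh**2) + np.sum(hl**2) + np.sum(hh**2))
        return total


def wavedec2(
    img: np.ndarray, bank: Union[str, WaveletFilterBank], levels: int
) -> DecompositionResult:
    """Multilevel 2D DWT: recursively decompose the LL subband."""
    bank = _as_bank(bank)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    approx = img
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for lev in range(levels):
        n = min(approx.shape)
        if n % 2 or n < len(bank):
            raise ValueError(
                f"cannot decompose level {lev + 1}: subband side {n} is "
                f"odd or shorter than the filter support {len(bank)}"
            )
        approx, lh, hl, hh = dwt2(approx, bank)
        details.append((lh, hl, hh))
    return DecompositionResult(levels=levels, approx=approx, details=details)


def waverec2(
    result: DecompositionResult, bank: Union[str, WaveletFilterBank]
) -> np.ndarray:
    """Reconstruct the image from a multilevel decomposition."""
    bank = _as_bank(bank)
    approx = result.approx
    for lh, hl, hh in reversed(result.details):
        approx = idwt2(approx, lh, hl, hh, bank)
    return approx


def extract_features(
    img: np.ndarray, bank: Union[str, WaveletFilterBank] = "haar", levels: int = 3
) -> np.ndarray:
    """Flatten the level-``levels`` approximation subband row-major.

    On a 256x256 slice with three levels the vector has
    (256 / 2^3)^2 = 1024 entries.
    """
    return wavedec2(img, bank, levels).approx.ravel(order="C")


# ---------------------------------------------------------------------------
# feature-matrix persistence

def features_to_frame(features: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    """Assemble the (label + coefficients) feature table."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or len(labels) != features.shape[0]:
        raise ValueError("features must be 2D with one label per row")
    df = pd.DataFrame(features, columns=[f"c{i}" for i in range(features.shape[1])])
    df.insert(0, "label", list(labels))
    return df


def save_features_csv(path: Union[str, Path], features: np.ndarray, labels: Sequence[str]) -> None:
    features_to_frame(features, labels).to_csv(path, index=False)


def load_features_csv(path: Union[str, Path]) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    labels = df["label"].to_numpy(dtype=str)
    X = df.drop(columns="label").to_numpy(dtype=np.float64)
    return X, labels


def save_features_npz(path: Union[str, Path], features: np.ndarray, labels: Sequence[str]) -> None:
    np.savez_compressed(path, features=np.asarray(features, dtype=np.float64),
                        labels=np.asarray(labels, dtype=str))


def load_features_npz(path: Union[str, Path]) -> tuple[np.ndarray, np.ndarray]:
    with np.load(path, allow_pickle=False) as f:
        return f["features"], f["labels"]
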