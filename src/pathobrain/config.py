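"""Pipeline configuration shared by the cross-validation driver and the CLI."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import yaml

from pathobrain.wavelet import FAMILIES


@dataclass
class PipelineConfig:
    """Every tunable of the four-stage cascade, with the defaults used
    throughout: Haar wavelet, 3 decomposition levels, 13 latent
    components, a 30-member ensemble on ceil(k/2)-dimensional
    subspaces with K=5 neighbours, and 5 repeats of stratified CV."""

    wavelet_name: str = "haar"
    levels: int = 3
    wiener_mode: str = "adaptive_local"
    wiener_window: int = 3
    denoise: bool = True
    resize: bool = False
    ppca_k: int = 13
    ppca_tol: float = 1e-6
    ppca_max_iter: int = 1000
    n_members: int = 30
    subspace_dim: Union[int, None] = None
    K: int = 5
    tie_rule: str = "pathological"
    n_folds: int = 5
    n_repeats: int = 5
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.wavelet_name not in FAMILIES:
            raise ValueError(f"wavelet_name must be one of {FAMILIES}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.wiener_mode not in ("adaptive_local", "frequency_domain"):
            raise ValueError("wiener_mode must be adaptive_local or frequency_domain")
        if self.wiener_window % 2 == 0 or self.wiener_window < 3:
            raise ValueError("wiener_window must be an odd integer >= 3")
        if self.ppca_k < 1 or self.ppca_tol <= 0 or self.ppca_max_iter < 1:
            raise ValueError("invalid PPCA settings")
        if self.n_members < 1 or self.K < 1:
            raise ValueError("invalid ensemble settings")
        if self.subspace_dim is not None and self.subspace_dim < 1:
            raise ValueError("subspace_dim must be >= 1 when given")
        if self.tie_rule not in ("pathological", "lowest_label"):
            raise ValueError("tie_rule must be pathological or lowest_label")
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("invalid cross-validation settings")
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
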