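"""Validated run configuration for the CLI and scripted pipelines."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the package defaults.

    Unknown keys in a YAML file are rejected on load; the resolved
    configuration is embedded in every run's outputs.
    """

    montage: str = "standard_1020_32"
    notch_hz: float = 50.0
    band: tuple[float, float] = (0.5, 40.0)
    fs_out: float = 128.0
    w: float = 2.0
    classify_w: float | None = None  # default: same as w
    ica: bool = True
    laplacian_k: int = 5
    t_mode: str = "mean_sq_dist"
    feature_top_fraction: float = 1.0 / 3.0
    kappa_max: int = 2
    damping: float = 0.9
    preference_mode: str = "median"
    alpha: float = 0.0
    epoch_filter: str = "none"
    bins: int = 8
    k_features: int = 32
    fractions: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))
    targets: tuple[str, ...] = ("valence", "arousal")
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.band = tuple(self.band)
        self.fractions = tuple(self.fractions)
        self.targets = tuple(self.targets)
        for width in (self.w, self.classify_w):
            if width is not None and width not in (2.0, 5.0, 10.0):
                # other widths work mechanically but are outside the studied set
                import warnings
                warnings.warn(
                    f"epoch width {width} s is outside the studied {{2,5,10}} s")
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 < lo < hi")
        if not all(0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if not (0.5 <= self.damping < 1.0):
            raise ValueError("damping must be in [0.5, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.to_dict().items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
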