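"""Pipeline configuration: every constant of the method, overridable.

The effective configuration is serialised next to every output so a run
can always be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class PipelineConfig:
    fs: float = 12.5  # nominal bolus sampling frequency, Hz
    variance_window_s: float = 1.5  # rolling variance of jerk magnitude
    smoothing_window_s: float = 8.0  # rolling mean, ~one contraction
    jvb_window_s: float = 40.0  # rolling median, ~one inter-contraction period
    block_s: float = 270.0  # feature block, three collar intervals
    log_base: str = "e"  # base for log JVB
    label_rule: str = "majority"  # collar-interval fusion: majority | all | any
    train_fraction: float = 0.8
    k_folds: int = 10
    C: float = 10.0  # SVM regularisation strength (near-hard-margin)
    seed: int = 0
    prominence_mode: str = "auto"  # auto (knee of sensitivity curve) | fixed
    prominence_threshold: float | None = None  # used when mode == fixed
    min_intervals_per_block: int = 2

    def __post_init__(self):
        if self.prominence_mode not in ("auto", "fixed"):
            raise ValueError("prominence_mode must be 'auto' or 'fixed'")
        if self.prominence_mode == "fixed" and self.prominence_threshold is None:
            raise ValueError("fixed prominence mode needs a threshold value")

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)
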