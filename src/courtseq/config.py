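"""Run configuration: every analysis option in one serializable object.

The config is embedded verbatim (plus a short hash) into every artifact the
pipeline writes, so a report can always be traced to the exact option set
that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

_CHOICES = {
    "lz_normalization": ("asymptotic",),
    "visual_labels": ("leg_tap", "idle+leg_tap"),
    "multimodal_rule": ("double_count_legtap", "single_count"),
    "half_split_rule": ("time", "count"),
    "entropy_rate_weights": ("empirical", "stationary"),
    "logistic_test": ("wald", "lr"),
    "paired_test": ("wilcoxon", "ttest"),
}


@dataclass(frozen=True)
class RunConfig:
    """Options governing windowing, metric definitions and test choices."""

    window_s: float = 300.0
    log_base: float = 2.0
    lz_normalization: str = "asymptotic"
    visual_labels: str = "leg_tap"
    multimodal_rule: str = "double_count_legtap"
    half_split_rule: str = "time"
    entropy_rate_weights: str = "empirical"
    logistic_test: str = "wald"
    paired_test: str = "wilcoxon"
    seed: int = 20080517

    def __post_init__(self) -> None:
        bad = {
            key: getattr(self, key)
            for key, options in _CHOICES.items()
            if getattr(self, key) not in options
        }
        if bad:
            raise ValueError(
                "invalid config values: "
                + ", ".join(f"{k}={v!r} (allowed: {_CHOICES[k]})" for k, v in sorted(bad.items()))
            )
        if self.window_s <= 0:
            raise ValueError("invalid config values: window_s must be positive")

    @property
    def visual_label_set(self) -> frozenset[str]:
        return frozenset(self.visual_labels.split("+"))

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping of key: value pairs")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)
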