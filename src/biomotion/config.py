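"""Run configuration with the model's default parameterization.

The defaults are the network parameterization used throughout the
experiments; any override is recorded so that run manifests stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["DEFAULT_PARAMS", "RunConfig"]

#: the experiment parameter block
DEFAULT_PARAMS: dict[str, float] = {
    "alpha": 5000.0,          # input scaling
    "lam": 0.95,              # smoothing update factor
    "eta": 0.01,              # instar learning rate
    "eta_mu": 0.0075,         # perspective angular learning rate
    "m_mu": 0.85,             # perspective angular momentum
    "theta": float(np.cos(np.pi / 3.0)),  # pattern recruitment threshold cos(60 deg)
    "b": 0.034,               # pattern threshold breadth
    "epsilon": 0.001,         # recruitment probability remainder
    "eta_l": 0.6,             # lateral inhibition learning rate
}


@dataclass
class RunConfig:
    """Experiment schedule and parameter overrides.

    ``params`` starts from :data:`DEFAULT_PARAMS`; overrides are kept in
    ``overrides`` for the manifest.
    """

    experiment: str = ""
    seed: int = 0
    n_repetitions: int = 20          # training repetitions per schedule
    interval_frames: int = 360       # frames per trial
    n_views: int = 4
    motion_kinds: tuple[str, ...] = ("gaitA", "gaitB", "gaitC")
    params: dict[str, float] = field(default_factory=dict)
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        for key, value in self.params.items():
            if key not in DEFAULT_PARAMS:
                raise KeyError(f"unknown parameter {key!r}")
            if value != DEFAULT_PARAMS[key]:
                self.overrides[key] = value
            merged[key] = value
        self.params = merged

    def manifest(self) -> dict:
        return {
            "experiment": self.experiment,
            "seed": self.seed,
            "n_repetitions": self.n_repetitions,
            "interval_frames": self.interval_frames,
            "n_views": self.n_views,
            "motion_kinds": list(self.motion_kinds),
            "params": {k: float(v) for k, v in self.params.items()},
            "overrides": {k: float(v) for k, v in self.overrides.items()},
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.manifest(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.pop("overrides", None)
        if "motion_kinds" in payload:
            payload["motion_kinds"] = tuple(payload["motion_kinds"])
        return cls(**payload)
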