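"""Validated run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig", "config_hash"]


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run.

    The resting analysis takes the first ``analysis_window_s`` seconds of
    each recording and splits them into ``n_epochs_rest`` consecutive epochs
    (default 30 s → 16 epochs of 1.875 s, an integer 960 samples at 512 Hz);
    the event analysis uses ``event_total_s`` epochs locked ``event_pre_s``
    before stimulus onset.  Unknown keys in a config file are rejected.
    """

    # recording / simulation geometry
    fs: float = 512.0
    n_channels: int = 32
    n_subjects_per_group: int = 10
    rest_duration_s: float = 35.0
    noise_sd_uv: float = 5.0
    group_effects: dict = field(
        default_factory=lambda: {
            "TD_like": {
                "mean_segment_s": 3.75,
                "coupling_density": 0.1,
                "coupling_range": [0.38, 0.5],
            },
            "ASD_like": {
                "mean_segment_s": 7.5,
                "coupling_density": 0.1,
                "coupling_range": [0.22, 0.34],
            },
        }
    )
    conditions: list = field(default_factory=lambda: ["rest", "event"])
    event_n_blocks: int = 4
    event_trials_per_block: int = 40
    event_segment_scale: float = 0.4
    gen_max_lag: int = 25

    # preprocessing
    analysis_window_s: float = 30.0
    n_epochs_rest: int = 16
    artifact_threshold_uv: float = 150.0
    event_pre_s: float = 0.1
    event_total_s: float = 0.5
    baseline_window_s: tuple = (0.0, 0.1)

    # connectivity
    max_lag_ms: float = 100.0
    active_mode: str = "weighted"
    active_threshold: float = 0.5

    # stability
    metric: str = "l1"
    null_model: str = "matrix_randomization"
    n_null_replicates: int = 100
    null_max_delete_s: float = 5.0

    # graph metrics
    negatives: str = "abs"
    n_modularity_restarts: int = 100

    # orchestration
    seed: int = 0
    out_dir: str = "runs/latest"
    simulate: bool = True
    input_dir: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def epoch_length_s(self) -> float:
        return self.analysis_window_s / self.n_epochs_rest

    @property
    def max_lag_samples(self) -> int:
        return int(round(self.max_lag_ms / 1000.0 * self.fs))

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_epochs_rest < 2:
            raise ValueError("need at least 2 resting epochs")
        n = self.epoch_length_s * self.fs
        if abs(n - round(n)) > 1e-6 or round(n) <= 0:
            raise ValueError(
                f"analysis window {self.analysis_window_s} s does not divide into "
                f"{self.n_epochs_rest} integer-sample epochs at {self.fs} Hz"
            )
        if self.metric not in ("l1", "l2", "cosine"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.null_model not in ("matrix_randomization", "temporal_shift"):
            raise ValueError(f"unknown null model {self.null_model!r}")
        if self.active_mode not in ("weighted", "binarized"):
            raise ValueError(f"unknown active mode {self.active_mode!r}")
        if self.rest_duration_s < self.analysis_window_s:
            raise ValueError("rest recordings must cover the analysis window")
        if self.null_model == "temporal_shift" and self.rest_duration_s < (
            self.analysis_window_s + self.null_max_delete_s
        ):
            raise ValueError(
                "temporal-shift null needs rest recordings of at least "
                "analysis_window_s + null_max_delete_s"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_window_s"] = list(d["baseline_window_s"])
        return d


def config_hash(config: RunConfig) -> str:
    """Short stable hash identifying a configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
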