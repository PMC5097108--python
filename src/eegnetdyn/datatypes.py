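"""Shared domain containers for the EEG network-dynamics pipeline.

All signal amplitudes are in nominal microvolts (µV), times in seconds and
lags in samples unless stated otherwise.  Containers are deliberately thin:
numerical work happens on the underlying :class:`numpy.ndarray` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MultichannelRecording",
    "TrialInfo",
    "Epoch",
    "ConnectivityMatrix",
    "LagMatrix",
    "DistanceVector",
    "NullDistribution",
    "StablePeriod",
    "NetworkMetrics",
    "AnovaResult",
]


@dataclass
class MultichannelRecording:
    """A channels × samples scalp recording.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in µV.
    fs
        Sampling rate in Hz.
    channel_labels
        One label per channel (10–20 montage names for the default montage).
    condition
        Optional condition name (e.g. ``"rest"`` or ``"event"``).
    artifact_positions
        ``(channel, sample)`` pairs of injected artifact deflections, if any.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    condition: Optional[str] = None
    artifact_positions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels × time) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class TrialInfo:
    """Event metadata attached to an event-locked epoch."""

    onset_sample: int
    condition: str
    correct: bool


@dataclass
class Epoch:
    """A fixed-length segment of a recording; the unit of one network."""

    samples: np.ndarray
    fs: float
    start_time: float
    trial: Optional[TrialInfo] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] == 0:
            raise ValueError("epoch samples must be non-empty channels × time")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted functional network for one epoch.

    ``weights[i, j]`` is the signed cross-correlation of channels *i* and *j*
    maximized in absolute value over lags; the diagonal is zero by
    convention and ``|weights| <= 1``.
    """

    weights: np.ndarray
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape[1] != n:
            raise ValueError("weights must be square")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class LagMatrix:
    """Integer sample lags achieving the maximal |cross-correlation|.

    Antisymmetric up to the sign convention: ``lags[i, j] == -lags[j, i]``.
    """

    lags: np.ndarray
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)


@dataclass
class DistanceVector:
    """Distances between consecutive connectivity matrices of one sequence."""

    values: np.ndarray
    metric: str = "l1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in ("l1", "l2", "cosine"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class NullDistribution:
    """Pooled inter-matrix distances under a named null model."""

    samples: np.ndarray
    model: str
    metric: str = "l1"
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.model not in ("matrix_randomization", "temporal_shift"):
            raise ValueError(f"unknown null model {self.model!r}")

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if len(self.samples) > 1 else 0.0


@dataclass
class StablePeriod:
    """A maximal run of stable transitions, spanning ``k+1`` epochs."""

    start_epoch: int
    end_epoch: int
    duration: float
    averaged_network: ConnectivityMatrix

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch + 1


@dataclass
class NetworkMetrics:
    """The six weighted-graph summary measures of one averaged network."""

    diameter: float
    radius: float
    char_path_length: float
    transitivity: float
    max_modularity: float
    global_efficiency: float
    disconnected: bool = False

    _FIELDS = (
        "diameter",
        "radius",
        "char_path_length",
        "transitivity",
        "max_modularity",
        "global_efficiency",
    )

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._FIELDS}


@dataclass(frozen=True)
class AnovaResult:
    """One effect row of a mixed two-way ANOVA."""

    effect: str  # 'condition', 'group' or 'condition x group'
    F: float
    df1: int
    df2: int
    p: float


def as_weights(matrix: "ConnectivityMatrix | np.ndarray") -> np.ndarray:
    """Return the raw weight array of a matrix or pass an ndarray through."""
    if isinstance(matrix, ConnectivityMatrix):
        return matrix.weights
    return np.asarray(matrix, dtype=float)
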