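"""Epoching, artifact/trial rejection and baseline correction.

Two epoching modes are supported, matching the two arms of the analysis:

* ``consecutive`` — a resting recording is tiled into non-overlapping
  fixed-length epochs (default: a 30 s analysis window split into 16 epochs
  of 1.875 s, i.e. 960 samples at 512 Hz).
* ``event_locked`` — one 500 ms epoch per behavioral trial, from 100 ms
  before stimulus onset to 400 ms after it.

Epochs whose absolute amplitude exceeds 150 µV on any channel (strictly) are
flagged as artifacts; event-locked epochs additionally require a correct
behavioral response to survive rejection.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np

from .datatypes import Epoch, MultichannelRecording, TrialInfo

__all__ = [
    "epoch_recording",
    "detect_artifacts",
    "reject_trials",
    "baseline_correct",
    "DEFAULT_ARTIFACT_THRESHOLD_UV",
    "DEFAULT_EVENT_PRE_S",
    "DEFAULT_EVENT_TOTAL_S",
]

logger = logging.getLogger(__name__)

DEFAULT_ARTIFACT_THRESHOLD_UV = 150.0
DEFAULT_EVENT_PRE_S = 0.1
DEFAULT_EVENT_TOTAL_S = 0.5


def _samples_for(epoch_length: float, fs: float) -> int:
    n = epoch_length * fs
    n_int = round(n)
    if n_int <= 0 or abs(n - n_int) > 1e-6:
        raise ValueError(
            f"epoch length {epoch_length} s is not a positive integer number of "
            f"samples at {fs} Hz"
        )
    return n_int


def epoch_recording(
    recording: MultichannelRecording,
    epoch_length: Optional[float] = None,
    mode: str = "consecutive",
    events: Optional[Iterable] = None,
    pre: float = DEFAULT_EVENT_PRE_S,
    total: float = DEFAULT_EVENT_TOTAL_S,
) -> list[Epoch]:
    """Segment a recording into epochs.

    Parameters
    ----------
    recording
        The input recording.
    epoch_length
        Epoch length in seconds (consecutive mode; must be an integer number
        of samples).
    mode
        ``"consecutive"`` or ``"event_locked"``.
    events
        For event_locked mode: an iterable of mappings (or a DataFrame's
        ``itertuples``/dict rows) with keys ``onset_sample``, ``condition``,
        ``correct``.
    pre, total
        Event window: epoch starts ``pre`` seconds before onset and lasts
        ``total`` seconds.  The window start is ``round(onset - pre*fs)``
        samples and the length is fixed at ``round(total*fs)`` samples so
        every event epoch has identical length.

    Returns
    -------
    list of Epoch
        Consecutive mode: ``floor(duration/epoch_length)`` epochs tiling the
        recording in order.  Event mode: one epoch per event fully inside the
        recording; events whose window would cross an edge are dropped with a
        logged warning.
    """
    X = recording.samples
    fs = recording.fs
    if mode == "consecutive":
        if epoch_length is None or epoch_length <= 0:
            raise ValueError("consecutive mode requires a positive epoch_length")
        n = _samples_for(epoch_length, fs)
        n_epochs = X.shape[1] // n
        return [
            Epoch(X[:, k * n : (k + 1) * n], fs=fs, start_time=k * n / fs)
            for k in range(n_epochs)
        ]
    if mode == "event_locked":
        if events is None:
            raise ValueError("event_locked mode requires events")
        n = _samples_for(total, fs)
        pre_samples = pre * fs
        epochs = []
        dropped = 0
        for ev in events:
            if not isinstance(ev, dict):
                ev = ev._asdict() if hasattr(ev, "_asdict") else dict(ev)
            onset = int(ev["onset_sample"])
            start = round(onset - pre_samples)
            if start < 0 or start + n > X.shape[1]:
                dropped += 1
                continue
            trial = TrialInfo(
                onset_sample=onset,
                condition=str(ev.get("condition", "event")),
                correct=bool(ev.get("correct", True)),
            )
            epochs.append(Epoch(X[:, start : start + n], fs=fs, start_time=start / fs, trial=trial))
        if dropped:
            logger.warning("dropped %d events whose window fell outside the recording", dropped)
        return epochs
    raise ValueError(f"unknown epoching mode {mode!r}")


def detect_artifacts(epoch: Epoch, threshold: float = DEFAULT_ARTIFACT_THRESHOLD_UV) -> bool:
    """True iff any sample on any channel strictly exceeds ``threshold`` µV in
    absolute amplitude."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return bool(np.any(np.abs(epoch.samples) > threshold))


def reject_trials(
    epochs: Sequence[Epoch],
    threshold: float = DEFAULT_ARTIFACT_THRESHOLD_UV,
) -> list[Epoch]:
    """Drop artifact epochs, and event epochs with incorrect responses.

    Resting (trial-less) epochs are judged on the amplitude criterion only.
    Order is preserved and rejection counts are logged.  Idempotent.
    """
    kept: list[Epoch] = []
    n_artifact = n_incorrect = 0
    for ep in epochs:
        if detect_artifacts(ep, threshold):
            n_artifact += 1
            continue
        if ep.trial is not None and not ep.trial.correct:
            n_incorrect += 1
            continue
        kept.append(ep)
    if n_artifact or n_incorrect:
        logger.info(
            "rejected %d artifact and %d incorrect-response epochs of %d",
            n_artifact,
            n_incorrect,
            len(epochs),
        )
    return kept


def baseline_correct(
    epoch: Epoch,
    baseline_window: tuple[float, float] = (0.0, DEFAULT_EVENT_PRE_S),
) -> Epoch:
    """Subtract each channel's mean over the baseline window.

    The window is expressed in seconds relative to the epoch start (default:
    the first 100 ms, i.e. the pre-stimulus portion).  Idempotent up to
    floating-point tolerance.
    """
    start_s, end_s = baseline_window
    fs = epoch.fs
    i0 = int(round(start_s * fs))
    i1 = int(round(end_s * fs))
    if not (0 <= i0 < i1 <= epoch.n_samples):
        raise ValueError(
            f"baseline window [{start_s}, {end_s}] s is empty or outside the epoch"
        )
    mean = epoch.samples[:, i0:i1].mean(axis=1, keepdims=True)
    return Epoch(epoch.samples - mean, fs=fs, start_time=epoch.start_time, trial=epoch.trial)
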