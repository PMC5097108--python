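"""Synthetic multichannel recordings with planted network regimes.

The generator emulates 32-channel, 512 Hz scalp-EEG-like data whose pairwise
lagged correlation structure switches between "regimes" over time.  Within a
regime, every coupled channel pair shares a common latent white-noise source,
mixed into the two channels at the pair's lag; the mixing fraction is chosen
so the population cross-correlation of a pair with coupling weight ``w``
(and no other couplings) is approximately ``w``.  Independent white noise is
added on top.  This is deliberately the *simplest* signal model that makes
every downstream statistic (lag-maximized correlation, inter-epoch network
distance, graph metrics) well defined; it makes no attempt at realistic EEG
spectra (1/f, alpha) or volume conduction.

Ground-truth regime schedules are returned alongside every recording so that
parameter-recovery tests can compare detected quasi-stable periods against
the planted segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import MultichannelRecording

__all__ = [
    "RegimeSegment",
    "RegimeSchedule",
    "GroupEffects",
    "ConditionSpec",
    "CohortSpec",
    "generate_recording",
    "random_schedule",
    "generate_cohort",
    "inject_artifacts",
    "generate_event_schedule",
]

#: RMS amplitude (µV) of the structured (non-noise) part of each channel,
#: in the range of typical scalp EEG; together with the default 5 µV sensor
#: noise the clean signal stays far inside ±100 µV (the 150 µV artifact
#: threshold sits beyond 7 SD) and pairwise correlations are attenuated by
#: only ~6% (factor A²/(A²+σ²)).
SIGNAL_RMS_UV = 20.0


@dataclass
class RegimeSegment:
    """One regime: a time interval with a fixed coupling graph and lag map."""

    start: float
    end: float
    coupling: np.ndarray  # n×n weights in [0, 1], symmetric, zero diagonal
    lags: np.ndarray  # n×n integer sample lags, antisymmetric

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.lags = np.asarray(self.lags, dtype=int)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class RegimeSchedule:
    """Ordered, contiguous regime segments covering a whole recording."""

    segments: list[RegimeSegment]

    def validate(self, max_lag: Optional[int] = None) -> None:
        if not self.segments:
            raise ValueError("schedule has no segments")
        prev_end = self.segments[0].start
        for seg in self.segments:
            if seg.duration <= 0:
                raise ValueError("segment with non-positive duration")
            if abs(seg.start - prev_end) > 1e-9:
                raise ValueError("segments must be contiguous and ordered")
            prev_end = seg.end
            W = seg.coupling
            if not np.allclose(W, W.T):
                raise ValueError("coupling graph must be symmetric")
            if np.any(np.abs(np.diag(W)) > 0):
                raise ValueError("coupling graph must have zero diagonal")
            if np.any((W < 0) | (W > 1)):
                raise ValueError("coupling weights must lie in [0, 1]")
            if not np.array_equal(seg.lags, -seg.lags.T):
                raise ValueError("lag map must be antisymmetric")
            if max_lag is not None and np.any(np.abs(seg.lags) > max_lag):
                raise ValueError(f"lags exceed the configured max lag {max_lag}")

    @property
    def span(self) -> float:
        """Total covered time in seconds."""
        return self.segments[-1].end - self.segments[0].start

    @property
    def n_channels(self) -> int:
        return self.segments[0].coupling.shape[0]

    def boundaries(self) -> list[float]:
        """Internal regime-change times (s), excluding the schedule ends."""
        return [seg.start for seg in self.segments[1:]]

    def to_json(self, path: str | Path) -> None:
        """Persist the schedule as a JSON sidecar."""
        obj = [
            {
                "start": seg.start,
                "end": seg.end,
                "coupling": seg.coupling.tolist(),
                "lags": seg.lags.tolist(),
            }
            for seg in self.segments
        ]
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegimeSchedule":
        obj = json.loads(Path(path).read_text())
        return cls(
            [
                RegimeSegment(d["start"], d["end"], np.asarray(d["coupling"]), np.asarray(d["lags"]))
                for d in obj
            ]
        )


def generate_recording(
    schedule: RegimeSchedule,
    n_channels: int = 32,
    fs: float = 512.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    condition: Optional[str] = None,
) -> MultichannelRecording:
    """Synthesize a recording realizing a regime schedule.

    Within each segment, for every channel pair ``(i, j)`` with coupling
    weight ``w > 0`` and lag ``k`` samples, a shared unit-variance source is
    mixed into both channels — channel *j* receiving the source delayed by
    ``k`` samples relative to channel *i* — with mixing fraction ``w`` (shares
    renormalized when a channel's couplings sum above one).  The remainder of
    each channel's structured variance is private, the whole structured part
    is scaled to :data:`SIGNAL_RMS_UV`, and independent Gaussian noise of SD
    ``noise_sd`` µV is added.  With a single coupled pair and ``noise_sd=0``
    the pair's lagged correlation is exactly 1 at the planted lag.
    """
    schedule.validate()
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if schedule.n_channels != n_channels:
        raise ValueError(
            f"schedule built for {schedule.n_channels} channels, requested {n_channels}"
        )

    rng = np.random.default_rng(seed)
    t0 = schedule.segments[0].start
    total = int(round(schedule.span * fs))
    out = np.zeros((n_channels, total))

    for seg in schedule.segments:
        s0 = int(round((seg.start - t0) * fs))
        s1 = int(round((seg.end - t0) * fs))
        length = s1 - s0
        W = seg.coupling
        # Renormalize coupling shares per channel so variances stay valid.
        load = W.sum(axis=1)
        scale_i = np.maximum(load, 1.0)
        block = np.zeros((n_channels, length))
        for i in range(n_channels):
            for j in range(i + 1, n_channels):
                w = W[i, j]
                if w <= 0:
                    continue
                k = int(seg.lags[i, j])
                if abs(k) >= length:
                    raise ValueError(
                        f"lag {k} not smaller than segment length {length} samples"
                    )
                z = rng.standard_normal(length + abs(k))
                if k >= 0:  # channel j delayed by k relative to channel i
                    zi, zj = z[k : k + length], z[:length]
                else:
                    zi, zj = z[:length], z[-k : -k + length]
                block[i] += np.sqrt(w / scale_i[i]) * zi
                block[j] += np.sqrt(w / scale_i[j]) * zj
        # Private component tops each channel up to unit variance.
        shared_var = (W / scale_i[:, None]).sum(axis=1)
        priv = np.sqrt(np.clip(1.0 - shared_var, 0.0, None))
        block += priv[:, None] * rng.standard_normal((n_channels, length))
        out[:, s0:s1] = SIGNAL_RMS_UV * block

    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return MultichannelRecording(out, fs=fs, condition=condition)


def random_schedule(
    duration: float,
    n_channels: int,
    mean_segment_s: float,
    coupling_density: float,
    coupling_range: tuple[float, float],
    max_lag: int,
    rng: np.random.Generator,
    min_segment_s: float = 0.5,
    ensure_connected: bool = True,
) -> RegimeSchedule:
    """Draw a random regime schedule.

    Segment durations are gamma-distributed with shape 3 and the given mean
    (floored at ``min_segment_s``), giving regimes a characteristic duration
    rather than a memoryless profile and little mass below one epoch.  Each
    segment's coupling graph starts from a random
    ring over all channels (``ensure_connected``; functional brain networks
    are connected, and a connected backbone keeps path-based graph measures
    finite and driven by the planted weights), plus every remaining pair
    independently with probability ``coupling_density``; weights are uniform
    in ``coupling_range`` and lags uniform in ``[-max_lag, max_lag]``.

    Because every coupled pair consumes part of a channel's variance budget,
    per-node coupling loads (row sums of the coupling graph) should stay at
    or below ~1 for the realized correlations to track the planted weights;
    with a ring backbone this means weights of at most ~0.5.
    """
    if mean_segment_s <= 0 or duration <= 0:
        raise ValueError("durations must be positive")
    segments: list[RegimeSegment] = []
    t = 0.0
    while t < duration - 1e-9:
        d = max(min_segment_s, rng.gamma(3.0, mean_segment_s / 3.0))
        end = min(t + d, duration)
        if duration - end < min_segment_s:  # absorb a too-short tail
            end = duration
        lo, hi = coupling_range
        W = np.zeros((n_channels, n_channels))
        K = np.zeros((n_channels, n_channels), dtype=int)
        iu, ju = np.triu_indices(n_channels, k=1)
        on = rng.random(len(iu)) < coupling_density
        if ensure_connected:
            ring = rng.permutation(n_channels)
            ring_mask = np.zeros((n_channels, n_channels), dtype=bool)
            for a, b in zip(ring, np.roll(ring, -1)):
                ring_mask[min(a, b), max(a, b)] = True
            on = on | ring_mask[iu, ju]
        w = rng.uniform(lo, hi, size=len(iu)) * on
        k = rng.integers(-max_lag, max_lag + 1, size=len(iu)) * on
        W[iu, ju] = w
        W[ju, iu] = w
        K[iu, ju] = k
        K[ju, iu] = -k
        segments.append(RegimeSegment(t, end, W, K))
        t = end
    return RegimeSchedule(segments)


@dataclass
class GroupEffects:
    """Per-group generative parameters controlling the planted effects.

    ``mean_segment_s`` drives the planted quasi-stable durations;
    ``coupling_range`` drives network diameter (weaker couplings → longer
    1/w path lengths → larger diameter); ``coupling_density`` sets how many
    pairs are coupled per regime.
    """

    mean_segment_s: float
    coupling_density: float = 0.4
    coupling_range: tuple[float, float] = (0.6, 0.9)
    segment_scale_by_condition: dict[str, float] = field(default_factory=dict)


@dataclass
class ConditionSpec:
    """Recording length and segment-duration scaling for one condition."""

    name: str
    duration_s: float = 35.0
    segment_scale: float = 1.0


@dataclass
class CohortSpec:
    """Design of a two-group, multi-condition synthetic cohort."""

    n_subjects_per_group: int
    group_effects: dict[str, GroupEffects]
    conditions: list[ConditionSpec]
    noise_sd: float = 5.0
    seed: int = 0
    n_channels: int = 32
    fs: float = 512.0
    max_lag: int = 25

    def validate(self) -> None:
        if self.n_subjects_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if not self.group_effects or not self.conditions:
            raise ValueError("group_effects and conditions must be non-empty")
        cond_names = {c.name for c in self.conditions}
        if len(cond_names) != len(self.conditions):
            raise ValueError("duplicate condition names")
        for g, eff in self.group_effects.items():
            if eff.mean_segment_s <= 0:
                raise ValueError(f"group {g}: mean_segment_s must be positive")
            extra = set(eff.segment_scale_by_condition) - cond_names
            if extra:
                raise ValueError(
                    f"group {g} references unknown conditions {sorted(extra)}"
                )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[tuple[str, str, str], MultichannelRecording], dict[tuple[str, str, str], RegimeSchedule]]:
    """Generate all recordings of a cohort plus their ground-truth schedules.

    Returns two dicts keyed by ``(group, subject_id, condition)``.  Each
    subject × condition gets an independent random stream spawned
    deterministically from ``spec.seed`` (one :class:`numpy.random.SeedSequence`
    child per recording, in group → subject → condition order), so cohorts are
    bit-reproducible and subjects independent.
    """
    spec.validate()
    recordings: dict[tuple[str, str, str], MultichannelRecording] = {}
    truth: dict[tuple[str, str, str], RegimeSchedule] = {}
    root = np.random.SeedSequence(spec.seed)
    n_rec = len(spec.group_effects) * spec.n_subjects_per_group * len(spec.conditions)
    children = iter(root.spawn(n_rec))
    for group in sorted(spec.group_effects):
        eff = spec.group_effects[group]
        for s in range(spec.n_subjects_per_group):
            subject = f"{group}_s{s:02d}"
            for cond in spec.conditions:
                child = next(children)
                rng = np.random.default_rng(child)
                scale = eff.segment_scale_by_condition.get(cond.name, cond.segment_scale)
                sched = random_schedule(
                    duration=cond.duration_s,
                    n_channels=spec.n_channels,
                    mean_segment_s=eff.mean_segment_s * scale,
                    coupling_density=eff.coupling_density,
                    coupling_range=eff.coupling_range,
                    max_lag=spec.max_lag,
                    rng=rng,
                )
                rec = generate_recording(
                    sched,
                    n_channels=spec.n_channels,
                    fs=spec.fs,
                    noise_sd=spec.noise_sd,
                    seed=rng.integers(2**31),
                    condition=cond.name,
                )
                key = (group, subject, cond.name)
                recordings[key] = rec
                truth[key] = sched
    return recordings, truth


def inject_artifacts(
    recording: MultichannelRecording,
    n_events: int,
    amplitude: float = 200.0,
    seed: int = 0,
) -> MultichannelRecording:
    """Add ``n_events`` single-sample deflections at random positions.

    Each event adds ``amplitude`` µV at a distinct (channel, sample) position;
    the positions are recorded in the returned recording's
    ``artifact_positions`` metadata so rejection logic can be validated.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    total = recording.samples.size
    if n_events > total:
        raise ValueError(f"n_events={n_events} exceeds sample count {total}")
    rng = np.random.default_rng(seed)
    samples = recording.samples.copy()
    flat = rng.choice(total, size=n_events, replace=False)
    positions = [(int(f) // recording.n_samples, int(f) % recording.n_samples) for f in flat]
    for ch, t in positions:
        samples[ch, t] += amplitude
    return MultichannelRecording(
        samples,
        fs=recording.fs,
        channel_labels=list(recording.channel_labels),
        condition=recording.condition,
        artifact_positions=positions,
    )


def generate_event_schedule(
    fs: float = 512.0,
    n_blocks: int = 4,
    trials_per_block: int = 40,
    stim_duration_s: float = 1.0,
    iti_s: float = 2.0,
    lead_in_s: float = 1.0,
    p_correct: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial table for the event-related design: blocks of visual stimuli.

    Mirrors a 4-block × 40-trial emotion-judgment design (stimulus 1000 ms,
    blank 2000 ms): blocks alternate isolated-face, isolated-body and two
    compound-stimulus categories; each trial carries an onset sample and a
    simulated behavioral-correctness flag (Bernoulli ``p_correct``).
    """
    rng = np.random.default_rng(seed)
    categories = ["faces", "bodies", "compound_a", "compound_b"]
    rows = []
    t = lead_in_s
    trial = 0
    for b in range(n_blocks):
        cat = categories[b % len(categories)]
        for _ in range(trials_per_block):
            rows.append(
                {
                    "trial": trial,
                    "block": b,
                    "category": cat,
                    "onset_sample": int(round(t * fs)),
                    "condition": "event",
                    "correct": bool(rng.random() < p_correct),
                }
            )
            t += stim_duration_s + iti_s
            trial += 1
    return pd.DataFrame(rows)


def generate_measure_table(
    n_per_group: int,
    group_condition_means: dict[tuple[str, str], float],
    subject_sd: float = 1.0,
    noise_sd: float = 1.0,
    measure: str = "mean_duration",
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort table of one summary measure drawn directly from a mixed model.

    Each subject gets a Gaussian random intercept (``subject_sd``) shared
    across conditions, plus independent Gaussian noise (``noise_sd``) per
    condition around the cell mean given in ``group_condition_means`` (keys
    ``(group, condition)``).  This generates the statistics stage's sampling
    model exactly, so ANOVA calibration (type-I error, power) can be studied
    with thousands of cohorts without simulating recordings.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    groups = sorted({g for g, _ in group_condition_means})
    conditions = sorted({c for _, c in group_condition_means})
    for g in groups:
        for c in conditions:
            if (g, c) not in group_condition_means:
                raise ValueError(f"missing cell mean for {(g, c)}")
    rows = []
    for g in groups:
        for s in range(n_per_group):
            subject = f"{g}_s{s:02d}"
            intercept = rng.normal(0.0, subject_sd)
            for c in conditions:
                rows.append(
                    {
                        "subject": subject,
                        "group": g,
                        "condition": c,
                        "measure": measure,
                        "value": group_condition_means[(g, c)]
                        + intercept
                        + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
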