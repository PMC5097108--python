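"""End-to-end orchestration: simulate → preprocess → connect → stability →
metrics → group statistics.

Every stage is a pure function of (inputs, config, seed): re-running the
same configuration bit-reproduces all outputs.  Null distributions are
pooled per condition across all subjects of both groups, exactly one
stability threshold (null mean − 2 SD) per condition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .connectivity import active_network, connectivity_matrix
from .datatypes import (
    AnovaResult,
    ConnectivityMatrix,
    DistanceVector,
    MultichannelRecording,
    NetworkMetrics,
    NullDistribution,
    StablePeriod,
)
from .graph_metrics import compute_metrics
from .group_stats import build_cohort_table, rm_anova, stepdown_ttest, summarize_subject
from .io import read_events, read_recording, save_matrix_stack, write_recording_text
from .preprocess import baseline_correct, epoch_recording, reject_trials
from .stability import (
    build_null_distribution,
    detect_stable_periods,
    distance_vector,
    stability_threshold,
)
from .synthetic import (
    CohortSpec,
    ConditionSpec,
    GroupEffects,
    generate_cohort,
    generate_event_schedule,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineResult", "SubjectConditionResult", "cohort_spec_from_config"]


@dataclass
class SubjectConditionResult:
    group: str
    subject: str
    condition: str
    matrices: list[ConnectivityMatrix]
    distances: Optional[DistanceVector]
    periods: list[StablePeriod] = field(default_factory=list)
    metrics: list[NetworkMetrics] = field(default_factory=list)


@dataclass
class PipelineResult:
    config: RunConfig
    subjects: dict[tuple[str, str, str], SubjectConditionResult]
    nulls: dict[str, NullDistribution]
    thresholds: dict[str, float]
    cohort_table: pd.DataFrame
    anova: dict[str, list[AnovaResult]]
    stepdown: pd.DataFrame
    run_dir: Optional[Path] = None


def _event_duration_s(config: RunConfig) -> float:
    n_trials = config.event_n_blocks * config.event_trials_per_block
    return 1.0 + n_trials * 3.0 + 1.0  # 1 s lead-in, 1 s stim + 2 s blank, 1 s tail


def cohort_spec_from_config(config: RunConfig) -> CohortSpec:
    conditions = []
    for name in config.conditions:
        if name == "rest":
            conditions.append(ConditionSpec("rest", duration_s=config.rest_duration_s))
        elif name == "event":
            conditions.append(
                ConditionSpec(
                    "event",
                    duration_s=_event_duration_s(config),
                    segment_scale=config.event_segment_scale,
                )
            )
        else:
            raise ValueError(f"unknown condition {name!r}")
    effects = {
        g: GroupEffects(
            mean_segment_s=e["mean_segment_s"],
            coupling_density=e.get("coupling_density", 0.4),
            coupling_range=tuple(e.get("coupling_range", (0.6, 0.9))),
        )
        for g, e in config.group_effects.items()
    }
    return CohortSpec(
        n_subjects_per_group=config.n_subjects_per_group,
        group_effects=effects,
        conditions=conditions,
        noise_sd=config.noise_sd_uv,
        seed=config.seed,
        n_channels=config.n_channels,
        fs=config.fs,
        max_lag=config.gen_max_lag,
    )


def _load_recordings(config: RunConfig) -> dict[tuple[str, str, str], MultichannelRecording]:
    """Load recordings named ``<group>__<subject>__<condition>.(tsv|edf)``."""
    input_dir = Path(config.input_dir)
    recordings = {}
    for path in sorted(input_dir.glob("*")):
        if path.suffix.lower() not in (".tsv", ".txt", ".edf"):
            continue
        parts = path.stem.split("__")
        if len(parts) != 3:
            raise ValueError(f"cannot parse group/subject/condition from {path.name}")
        group, subject, condition = parts
        recordings[(group, subject, condition)] = read_recording(path, condition=condition)
    if not recordings:
        raise ValueError(f"no recordings found in {input_dir}")
    return recordings


def _connect_epochs(epochs, config: RunConfig) -> list[ConnectivityMatrix]:
    mats = []
    for k, ep in enumerate(epochs):
        W, _ = connectivity_matrix(ep, max_lag=config.max_lag_samples, epoch_index=k)
        mats.append(active_network(W, mode=config.active_mode, threshold=config.active_threshold))
    return mats


def _process_rest(rec: MultichannelRecording, config: RunConfig) -> list[ConnectivityMatrix]:
    n_window = int(round(config.analysis_window_s * rec.fs))
    trimmed = MultichannelRecording(
        rec.samples[:, :n_window], fs=rec.fs, channel_labels=list(rec.channel_labels),
        condition=rec.condition,
    )
    epochs = epoch_recording(trimmed, epoch_length=config.epoch_length_s)
    epochs = reject_trials(epochs, threshold=config.artifact_threshold_uv)
    return _connect_epochs(epochs, config)


def _process_event(
    rec: MultichannelRecording, events: pd.DataFrame, config: RunConfig
) -> list[ConnectivityMatrix]:
    epochs = epoch_recording(
        rec,
        mode="event_locked",
        events=events.to_dict("records"),
        pre=config.event_pre_s,
        total=config.event_total_s,
    )
    epochs = reject_trials(epochs, threshold=config.artifact_threshold_uv)
    epochs = [baseline_correct(ep, config.baseline_window_s) for ep in epochs]
    return _connect_epochs(epochs, config)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Run the full analysis and (optionally) persist a run directory."""
    config.validate()
    chash = config_hash(config)

    # --- stage 1: inputs -------------------------------------------------
    events_by_key: dict[tuple[str, str, str], pd.DataFrame] = {}
    if config.simulate:
        spec = cohort_spec_from_config(config)
        recordings, truth = generate_cohort(spec)
        for idx, key in enumerate(sorted(recordings)):
            if key[2] == "event":
                ev_seed = np.random.SeedSequence((config.seed, 7919, idx))
                events_by_key[key] = generate_event_schedule(
                    fs=config.fs,
                    n_blocks=config.event_n_blocks,
                    trials_per_block=config.event_trials_per_block,
                    seed=ev_seed,
                )
    else:
        recordings = _load_recordings(config)
        truth = {}
        for key in recordings:
            if key[2] == "event":
                ev_path = Path(config.input_dir) / ("__".join(key) + "_events.tsv")
                events_by_key[key] = read_events(ev_path)

    # --- stage 2+3: preprocess and connectivity --------------------------
    subjects: dict[tuple[str, str, str], SubjectConditionResult] = {}
    for key in sorted(recordings):
        group, subject, condition = key
        rec = recordings[key]
        if condition == "rest":
            mats = _process_rest(rec, config)
        else:
            mats = _process_event(rec, events_by_key[key], config)
        dvec = distance_vector(mats, config.metric) if len(mats) >= 2 else None
        subjects[key] = SubjectConditionResult(group, subject, condition, mats, dvec)

    # --- stage 4: null distributions and thresholds ----------------------
    conditions = sorted({k[2] for k in subjects})
    null_seed_root = np.random.SeedSequence((config.seed, 104729))
    null_seeds = null_seed_root.generate_state(len(conditions))
    nulls: dict[str, NullDistribution] = {}
    thresholds: dict[str, float] = {}
    for cond, nseed in zip(conditions, null_seeds):
        keys = [k for k in sorted(subjects) if k[2] == cond]
        if config.null_model == "matrix_randomization":
            inputs = [subjects[k].matrices for k in keys if len(subjects[k].matrices) >= 2]
        else:
            inputs = [recordings[k] for k in keys]
        null = build_null_distribution(
            inputs,
            model=config.null_model,
            metric=config.metric,
            n_replicates=config.n_null_replicates,
            seed=int(nseed % 2**31),
            condition=cond,
            epoch_length=config.epoch_length_s if cond == "rest" else config.event_total_s,
            max_lag=config.max_lag_samples,
            max_delete=config.null_max_delete_s,
            final_length=config.analysis_window_s,
        )
        nulls[cond] = null
        thresholds[cond] = stability_threshold(null)
        logger.info(
            "condition %s: null mean %.3f sd %.3f threshold %.3f (%d samples)",
            cond, null.mean, null.sd, thresholds[cond], len(null.samples),
        )

    # --- stage 5: stable periods and graph metrics -----------------------
    metrics_seed = int(np.random.SeedSequence((config.seed, 15485863)).generate_state(1)[0] % 2**31)
    for key, sub in subjects.items():
        if sub.distances is None:
            continue
        epoch_len = config.epoch_length_s if key[2] == "rest" else config.event_total_s
        sub.periods = detect_stable_periods(
            sub.distances, thresholds[key[2]], epoch_len, sub.matrices
        )
        sub.metrics = [
            compute_metrics(p.averaged_network, n_restarts=config.n_modularity_restarts,
                            seed=metrics_seed)
            for p in sub.periods
        ]

    # --- stage 6: cohort table and group statistics ----------------------
    frames = [
        summarize_subject(sub.periods, sub.metrics, condition=key[2],
                          subject=key[1], group=key[0])
        for key, sub in sorted(subjects.items())
    ]
    table = build_cohort_table(frames)
    anova: dict[str, list[AnovaResult]] = {}
    stepdown_rows = []
    if len(conditions) >= 2 and len({k[0] for k in subjects}) >= 2:
        for measure in table["measure"].unique():
            try:
                anova[measure] = rm_anova(table, measure)
            except ValueError as exc:
                logger.warning("ANOVA skipped for %s: %s", measure, exc)
            for cond in conditions:
                try:
                    t, df, p = stepdown_ttest(table, measure, cond)
                    stepdown_rows.append(
                        {"measure": measure, "condition": cond, "t": t, "df": df, "p": p}
                    )
                except ValueError as exc:
                    logger.warning("t test skipped for %s/%s: %s", measure, cond, exc)
    stepdown = pd.DataFrame(stepdown_rows)

    result = PipelineResult(
        config=config,
        subjects=subjects,
        nulls=nulls,
        thresholds=thresholds,
        cohort_table=table,
        anova=anova,
        stepdown=stepdown,
    )
    if write_outputs:
        result.run_dir = _write_run_dir(result, recordings, truth, chash)
    return result


def _write_table(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_run_dir(result: PipelineResult, recordings, truth, chash: str) -> Path:
    config = result.config
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config_hash": chash,
        "config": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    dist_rows, period_rows, metric_rows = [], [], []
    for key, sub in sorted(result.subjects.items()):
        stem = "__".join(key)
        save_matrix_stack(sub.matrices, mat_dir / f"{stem}.npz", meta={"config_hash": chash})
        if sub.distances is not None:
            for t, v in enumerate(sub.distances.values):
                dist_rows.append(
                    {"group": key[0], "subject": key[1], "condition": key[2],
                     "transition": t, "distance": v}
                )
        for pid, (p, m) in enumerate(zip(sub.periods, sub.metrics)):
            period_rows.append(
                {"group": key[0], "subject": key[1], "condition": key[2], "period": pid,
                 "start_epoch": p.start_epoch, "end_epoch": p.end_epoch,
                 "duration_s": p.duration}
            )
            metric_rows.append(
                {"group": key[0], "subject": key[1], "condition": key[2], "period": pid,
                 "duration_s": p.duration, **m.as_dict()}
            )
    _write_table(pd.DataFrame(dist_rows), out / "distances.tsv", chash)
    _write_table(pd.DataFrame(period_rows), out / "stable_periods.tsv", chash)
    _write_table(pd.DataFrame(metric_rows), out / "metrics.tsv", chash)
    _write_table(result.cohort_table, out / "cohort_table.tsv", chash)

    null_summary = {
        cond: {
            "model": null.model,
            "metric": null.metric,
            "mean": null.mean,
            "sd": null.sd,
            "n_samples": int(len(null.samples)),
            "threshold": result.thresholds[cond],
        }
        for cond, null in result.nulls.items()
    }
    (out / "null_distributions.json").write_text(json.dumps(null_summary, indent=1))

    anova_rows = [
        {"measure": measure, "effect": r.effect, "F": r.F, "df1": r.df1, "df2": r.df2, "p": r.p}
        for measure, rows in result.anova.items()
        for r in rows
    ]
    anova_df = pd.DataFrame(anova_rows)
    if not anova_df.empty:
        # transparency column: Holm adjustment across measures per effect
        from .group_stats import holm_adjust

        anova_df["p_holm"] = np.nan
        for effect, idx in anova_df.groupby("effect").groups.items():
            anova_df.loc[idx, "p_holm"] = holm_adjust(anova_df.loc[idx, "p"].to_numpy())
    _write_table(anova_df, out / "anova.tsv", chash)
    _write_table(result.stepdown, out / "stepdown_ttests.tsv", chash)
    return out


def write_simulated_cohort(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort and persist recordings, events and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort_spec_from_config(config)
    recordings, truth = generate_cohort(spec)
    for idx, key in enumerate(sorted(recordings)):
        stem = "__".join(key)
        write_recording_text(recordings[key], out / f"{stem}.tsv")
        truth[key].to_json(out / f"{stem}_schedule.json")
        if key[2] == "event":
            ev = generate_event_schedule(
                fs=config.fs,
                n_blocks=config.event_n_blocks,
                trials_per_block=config.event_trials_per_block,
                seed=np.random.SeedSequence((config.seed, 7919, idx)),
            )
            ev.to_csv(out / f"{stem}_events.tsv", sep="\t", index=False)
    return out
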