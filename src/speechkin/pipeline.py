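"""End-to-end orchestration: recordings -> kinematic records -> group stats.

Per trial the stages run in order: head-motion correction, low-pass
filtering, differentiation, utterance segmentation, syllable-cycle
extraction. Any stage failure drops that trial with a logged reason; a
participant enters the analysis only with at least ``analysis.min_trials``
valid repetitions (at most the first ``analysis.max_trials`` are used).
Participants whose averaged dynamic ranges exceed a configured normative
mean by more than 3 SD are flagged and excluded from group statistics.

Given identical inputs, configuration and seed, a run is deterministic
and its output tables are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coordination, head_frame, io, metrics, preprocess, segmentation
from .config import RunConfig
from .errors import SpeechKinError
from .io import MarkerRecording, ParticipantMeta

logger = logging.getLogger("speechkin")

__all__ = ["QCReport", "CohortResult", "run_participant", "run_cohort", "group_summary"]

PHRASE_MEASURES = [
    "displacement_dynamic_range_mm",
    "velocity_dynamic_range_mm_s",
    "sentence_duration_s",
    "la_index",
]


@dataclass
class QCReport:
    """Machine-readable per-participant quality control."""

    participant_id: str
    sentence_id: str
    n_input_trials: int = 0
    used_trial_ids: list[str] = field(default_factory=list)
    dropped: list[dict] = field(default_factory=list)  # trial_id, stage, reason
    participant_dropped_reason: str | None = None

    def drop(self, trial_id: str, stage: str, reason: str) -> None:
        self.dropped.append({"trial_id": trial_id, "stage": stage, "reason": reason})
        logger.info("trial %s dropped at %s: %s", trial_id, stage, reason)


def _trial_segment(
    rec: MarkerRecording, config: RunConfig, extract_cycles: bool = True
) -> tuple[segmentation.UtteranceSegment, list[segmentation.MovementCycle]]:
    """Run one recording through correction, smoothing and segmentation."""
    if config.head_correction:
        transforms = head_frame.estimate_head_transforms(rec)
        upper = head_frame.project_lip_trajectory(rec, transforms, "upper_lip")
        lower = head_frame.project_lip_trajectory(rec, transforms, "lower_lip")
    else:
        upper = preprocess.Trajectory(
            rec.markers["upper_lip"][:, 2], rec.sample_rate, "upper_lip"
        )
        lower = preprocess.Trajectory(
            rec.markers["lower_lip"][:, 2], rec.sample_rate, "lower_lip"
        )
    # both lips share the filter; one batched call halves the overhead
    from scipy.signal import sosfiltfilt

    sos = preprocess._butter_sos(config.filter.order, config.filter.cutoff_hz, rec.sample_rate)
    both = sosfiltfilt(sos, np.vstack([upper.samples, lower.samples]), axis=-1)
    upper = preprocess.Trajectory(both[0], rec.sample_rate, "upper_lip")
    lower = preprocess.Trajectory(both[1], rec.sample_rate, "lower_lip")
    vel = preprocess.differentiate(lower)
    seg = segmentation.segment_utterance(
        {"upper_lip": upper, "lower_lip": lower},
        vel,
        prominence_frac=config.segmentation.prominence_frac,
    )
    cycles: list[segmentation.MovementCycle] = []
    if extract_cycles:
        try:
            cycles = segmentation.extract_movement_cycles(seg, config.segmentation.cycles)
        except SpeechKinError as exc:
            logger.info("cycle extraction failed for %s: %s", rec.trial_id, exc)
    return seg, cycles


def run_participant(
    recordings: list[MarkerRecording],
    config: RunConfig | None = None,
    sentence_id: str = "BBAP",
) -> tuple[metrics.KinematicRecord | None, QCReport]:
    """Analyse one participant's recordings for one sentence.

    Returns ``(record, qc)``; the record is ``None`` when fewer than
    ``analysis.min_trials`` trials survive, with the reason in the QC
    report.
    """
    config = config or RunConfig()
    pid = recordings[0].participant_id if recordings else "unknown"
    qc = QCReport(participant_id=pid, sentence_id=sentence_id, n_input_trials=len(recordings))

    segments: list[segmentation.UtteranceSegment] = []
    cycles_per_trial: list[list[segmentation.MovementCycle]] = []
    for rec in recordings:
        if len(segments) >= config.analysis.max_trials:
            break
        try:
            seg, cycles = _trial_segment(rec, config)
        except SpeechKinError as exc:
            qc.drop(rec.trial_id, type(exc).__name__, str(exc))
            continue
        segments.append(seg)
        cycles_per_trial.append(cycles)
        qc.used_trial_ids.append(rec.trial_id)

    if len(segments) < config.analysis.min_trials:
        qc.participant_dropped_reason = (
            f"insufficient trials: {len(segments)} < {config.analysis.min_trials}"
        )
        logger.info("participant %s dropped: %s", pid, qc.participant_dropped_reason)
        return None, qc

    trials = segmentation.TrialSet(participant_id=pid, sentence_id=sentence_id, segments=segments)
    la = coordination.la_index(
        trials,
        n_points=config.sti.n_points,
        n_grid=config.sti.n_grid,
        include_start=config.sti.include_start,
        sd_ddof=config.sti.sd_ddof,
    )
    record = metrics.summarize_participant(
        trials,
        cycles_per_trial,
        la_index=la.la_index,
        coverage=config.dynamic_range.coverage,
        min_trials=config.analysis.min_trials,
        normative={
            k: tuple(v) for k, v in config.exclusion.normative.items()
        }
        or None,
        k_sd=config.exclusion.k_sd,
    )
    return record, qc


@dataclass
class CohortResult:
    """All cohort-level outputs of one run."""

    records: pd.DataFrame  # one row per participant x sentence
    group_summary: dict  # per-cell means/SDs per measure
    levene: dict  # measure -> {statistic, p}
    anova: dict  # measure -> effect table (DataFrame)
    posthoc: dict  # measure -> pairwise table (DataFrame)
    qc: list[QCReport]


def group_summary(records: pd.DataFrame, measures: list[str] | None = None) -> dict:
    """Per (group, sex) cell mean and SD for each phrase measure."""
    measures = measures or [m for m in PHRASE_MEASURES if m in records.columns]
    out: dict = {}
    for (group, sex), sub in records.groupby(["group", "sex"]):
        cell = f"{group}_{sex}"
        out[cell] = {"n": int(len(sub))}
        for m in measures:
            vals = sub[m].dropna()
            out[cell][m] = {
                "mean": round(float(vals.mean()), 6) if len(vals) else None,
                "sd": round(float(vals.std(ddof=1)), 6) if len(vals) > 1 else None,
            }
    return out


def _cohort_stats(records: pd.DataFrame, measures: list[str]):
    """Levene, 2x2 ANOVA (within = sentence when >1) and post hocs per measure."""
    from . import stats as _stats

    analysed = records[~records["excluded"]]
    levene: dict = {}
    anova: dict = {}
    posthoc: dict = {}
    n_sentences = analysed["sentence_id"].nunique()
    cell = analysed["group"] + "_" + analysed["sex"]
    for m in measures:
        sub = analysed.dropna(subset=[m])
        if sub.empty or sub.groupby(["group", "sex"]).ngroups < 4:
            logger.warning("stats skipped for %s: empty design cell", m)
            continue
        within = ["sentence_id"] if n_sentences > 1 else None
        try:
            stat, p = _stats.levene_test(
                sub.groupby("participant_id")[m].mean().to_numpy(),
                sub.groupby("participant_id")[["group", "sex"]]
                .first()
                .agg("_".join, axis=1)
                .to_numpy(),
            )
            levene[m] = {"statistic": round(stat, 6), "p": round(p, 6)}
            anova[m] = _stats.mixed_anova(
                sub, dv=m, subject="participant_id", between=["group", "sex"], within=within
            ).table
            per_subject = sub.groupby("participant_id").agg(
                value=(m, "mean"), cell=("group", "first"), sex=("sex", "first")
            )
            posthoc[m] = _stats.tukey_kramer(
                per_subject["value"].to_numpy(),
                (per_subject["cell"] + "_" + per_subject["sex"]).to_numpy(),
            ).table
        except SpeechKinError as exc:
            logger.warning("stats skipped for %s: %s", m, exc)
    return levene, anova, posthoc


def run_cohort(
    recordings: dict[str, list[MarkerRecording]],
    metas: list[ParticipantMeta],
    config: RunConfig | None = None,
    sentence_id: str = "BBAP",
    out_dir: str | Path | None = None,
) -> CohortResult:
    """Analyse a cohort of participants and compute group statistics.

    ``recordings`` maps participant id to that participant's trial
    recordings for one sentence. Every participant in ``metas`` ends up
    either in the results table or dropped with a reason in QC.
    """
    config = config or RunConfig()
    meta_by_id = {m.participant_id: m for m in metas}
    missing = sorted(set(recordings) - set(meta_by_id))
    if missing:
        raise SpeechKinError(f"recordings without metadata: {missing}")

    rows = []
    qcs: list[QCReport] = []
    for pid in sorted(meta_by_id):
        meta = meta_by_id[pid]
        recs = recordings.get(pid, [])
        record, qc = run_participant(recs, config, sentence_id=sentence_id)
        qcs.append(qc)
        if record is None:
            continue
        row = record.to_row()
        row["group"] = meta.group
        row["sex"] = meta.sex
        rows.append(row)

    records = pd.DataFrame(rows)
    if records.empty:
        raise SpeechKinError("no participant produced enough valid trials")
    measures = [m for m in PHRASE_MEASURES if m in records.columns]
    summary = group_summary(records, measures)
    levene, anova, posthoc = _cohort_stats(records, measures)
    result = CohortResult(
        records=records,
        group_summary=summary,
        levene=levene,
        anova=anova,
        posthoc=posthoc,
        qc=qcs,
    )
    if out_dir is not None:
        write_outputs(result, config, Path(out_dir))
    return result


def write_outputs(result: CohortResult, config: RunConfig, out_dir: Path) -> None:
    """Write all result tables, QC and the resolved configuration."""
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_results_table(
        [row for _, row in result.records.iterrows()], out_dir / "records.tsv"
    )
    with open(out_dir / "group_summary.json", "w") as fh:
        json.dump(result.group_summary, fh, indent=2, sort_keys=True)
    with open(out_dir / "levene.json", "w") as fh:
        json.dump(result.levene, fh, indent=2, sort_keys=True)
    for m, table in result.anova.items():
        table.to_csv(out_dir / f"anova_{m}.tsv", sep="\t", index=False, float_format="%.6g")
    for m, table in result.posthoc.items():
        table.to_csv(out_dir / f"posthoc_{m}.tsv", sep="\t", index=False, float_format="%.6g")
    qc_rows = []
    for qc in result.qc:
        qc_rows.append(
            {
                "participant_id": qc.participant_id,
                "sentence_id": qc.sentence_id,
                "n_input_trials": qc.n_input_trials,
                "n_used": len(qc.used_trial_ids),
                "n_dropped_trials": len(qc.dropped),
                "participant_dropped_reason": qc.participant_dropped_reason or "",
            }
        )
    pd.DataFrame(qc_rows).to_csv(out_dir / "qc.tsv", sep="\t", index=False)
    config.to_yaml(out_dir / "resolved_config.yaml")
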