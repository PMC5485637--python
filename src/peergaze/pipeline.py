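"""End-to-end orchestration: cleaning -> QC -> events/AOI -> inference.

``run_pipeline`` drives the whole chain on an in-memory dataset (as produced
by :func:`peergaze.simulate.simulate_dataset` or loaded from a dataset
directory via :func:`peergaze.io.read_dataset_dir`) and returns every
intermediate table plus a run manifest.  All stages are deterministic, so a
rerun with the same inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import FixationParams, aoi_fixation_time, compute_velocity, \
    detect_fixations
from .geometry import ScreenGeometry, scene_center_px
from .inference import ModelAveragingResult, build_model_table, run_analysis
from .preprocess import CleaningConfig, blink_mask, detect_blinks, \
    drift_correct_trial, flag_validity, participant_y_correction, \
    repair_invalid, smooth_gaze, smooth_pupil
from .qc import QCConfig, qc_participant, qc_trial, segment_trials
from .questionnaires import score_pds, score_sas_a
from .stream import GazeStream

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult",
           "run_pipeline", "preprocess_participant", "score_participants"]


@dataclass(frozen=True)
class PipelineConfig:
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    fixation: FixationParams = field(default_factory=FixationParams)
    qc: QCConfig = field(default_factory=QCConfig)
    covariate: str = "anxiety"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        def build(klass, key):
            section = raw.get(key, {})
            if key == "geometry":
                for tup in ("screen_px", "scene_px"):
                    if tup in section:
                        section[tup] = tuple(section[tup])
            if key == "cleaning" and "pupil_physiological_range_mm" in section:
                section["pupil_physiological_range_mm"] = tuple(
                    section["pupil_physiological_range_mm"])
            return klass(**section)
        return cls(geometry=build(ScreenGeometry, "geometry"),
                   cleaning=build(CleaningConfig, "cleaning"),
                   fixation=build(FixationParams, "fixation"),
                   qc=build(QCConfig, "qc"),
                   covariate=raw.get("covariate", "anxiety"),
                   seed=int(raw.get("seed", 0)))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    n_participants_in: int
    n_participants_kept: int
    n_trials_in: int
    n_trials_valid: int
    exclusion_tally: dict[str, int]
    wall_time_s: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: RunManifest
    qc_trials: pd.DataFrame
    qc_participants: pd.DataFrame
    fixations: pd.DataFrame
    metrics: pd.DataFrame
    records: pd.DataFrame
    model: ModelAveragingResult | None


def preprocess_participant(stream: GazeStream, events: pd.DataFrame,
                           design_p: pd.DataFrame,
                           aois: dict[int, list],
                           config: PipelineConfig,
                           ) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Run cleaning, QC and fixation/AOI extraction for one participant.

    Returns (qc decisions, fixation table, per-trial metrics table); metrics
    cover only QC-valid trials.
    """
    geom, clean, qcc = config.geometry, config.cleaning, config.qc
    validity = flag_validity(stream, geom, clean)
    sm = smooth_gaze(stream, clean)
    sm = smooth_pupil(sm, clean)
    blinks = detect_blinks(sm, clean)
    mask = validity & ~blink_mask(sm, blinks)

    segments = segment_trials(sm, events, design_p)
    seg_masks = [mask[s.start_index:s.start_index + s.stream.n] for s in segments]
    cross = scene_center_px(geom)
    windows = [(s.window.fixation_onset_ms, s.window.scene_onset_ms)
               for s in segments]
    corrected, y_shift = participant_y_correction(
        [s.stream for s in segments], cross, windows, clean, seg_masks)
    if y_shift:
        logger.info("participant y-correction applied: %.1f px", y_shift)

    decisions = []
    fix_rows = []
    metric_rows = []
    for seg, st, m in zip(segments, corrected, seg_masks):
        win = seg.window
        st, drift = drift_correct_trial(
            st, cross, (win.fixation_onset_ms, win.scene_onset_ms), clean,
            validity=m)
        decision = qc_trial(seg, m, qcc,
                            drift_uncorrectable=drift.reason == "no_valid_cross_samples")
        decisions.append(decision)
        if not decision.valid:
            continue
        repaired = repair_invalid(st, m)
        pad_ms = 50.0
        i0, i1 = repaired.window_indices(win.scene_onset_ms - pad_ms,
                                         win.scene_offset_ms + pad_ms)
        sl = repaired.slice(i0, i1)
        gx, gy = sl.eye(clean.analysis_eye)
        fixations = detect_fixations(sl.t_ms, gx, gy, config.fixation, geom)
        for f in fixations:
            fix_rows.append({"trial_id": win.trial_id, "onset_ms": f.onset_ms,
                             "offset_ms": f.offset_ms, "x_px": f.centroid_px[0],
                             "y_px": f.centroid_px[1],
                             "duration_ms": f.duration_ms})
        tm = aoi_fixation_time(
            fixations, aois, win.scene_id,
            (win.scene_onset_ms, win.scene_offset_ms), geom,
            trial_id=win.trial_id, perspective=win.perspective,
            valence=win.valence)
        metric_rows.append({
            "trial_id": win.trial_id, "scene_id": win.scene_id,
            "perspective": win.perspective, "valence": win.valence,
            "total_aoi_fixation_ms": tm.total_aoi_fixation_ms,
            "n_fixations": tm.n_fixations})
    return decisions, pd.DataFrame(fix_rows), pd.DataFrame(metric_rows)


def score_participants(participants: pd.DataFrame) -> pd.DataFrame:
    """Attach anxiety (SAS-A total) and pds_score columns from raw items."""
    out = participants.copy()
    sas_cols = sorted(c for c in out.columns if c.startswith("sas_"))
    if sas_cols and "anxiety" not in out.columns:
        out["anxiety"] = [score_sas_a(list(r)).total
                          for r in out[sas_cols].to_numpy()]
    pds_cols = sorted(c for c in out.columns if c.startswith("pds_"))
    if len(pds_cols) == 4 and "menarche" in out.columns:
        out["pds_score"] = [
            score_pds(list(r), bool(m))
            for r, m in zip(out[pds_cols].to_numpy(), out["menarche"])]
    return out


def run_pipeline(dataset: dict | object, config: PipelineConfig,
                 fit_model: bool = True) -> PipelineResult:
    """Run the full analysis on an in-memory dataset.

    ``dataset`` is either the dict returned by
    :func:`peergaze.io.read_dataset_dir` or a
    :class:`~peergaze.simulate.SimulatedDataset`.
    """
    t0 = time.perf_counter()
    if not isinstance(dataset, dict):
        dataset = {"design": dataset.design,
                   "participants": dataset.participants,
                   "ratings": dataset.ratings, "aois": dataset.aois,
                   "streams": dataset.streams, "events": dataset.events}
    design = dataset["design"]
    participants = score_participants(dataset["participants"])

    all_decisions: dict[str, list] = {}
    fix_frames, metric_frames, part_rows = [], [], []
    tally: dict[str, int] = {}
    for pid in sorted(dataset["streams"]):
        stream = dataset["streams"][pid]
        events_p = dataset["events"]
        if "participant_id" in events_p.columns:
            events_p = events_p[events_p["participant_id"] == pid]
        design_p = design[design["participant_id"] == pid]
        decisions, fixations, metrics = preprocess_participant(
            stream, events_p, design_p, dataset["aois"], config)
        all_decisions[pid] = decisions
        keep, counts = qc_participant(decisions, design_p, config.qc)
        part_rows.append({"participant_id": pid, "keep": keep, **{
            f"valid_{k}": v for k, v in sorted(counts.items())}})
        for d in decisions:
            for r in d.reasons:
                tally[r] = tally.get(r, 0) + 1
        if keep:
            metrics = metrics.copy()
            metrics["participant_id"] = pid
            metric_frames.append(metrics)
            fix_frames.append(fixations)

    qc_trials = pd.DataFrame([{
        "trial_id": d.trial_id, "valid": d.valid,
        "reasons": ";".join(d.reasons),
        "invalid_fraction": d.invalid_fraction,
        "longest_run_after_fix_ms": d.longest_run_after_fix_ms,
        "longest_run_before_offset_ms": d.longest_run_before_offset_ms,
    } for ds in all_decisions.values() for d in ds])
    qc_parts = pd.DataFrame(part_rows)
    metrics = (pd.concat(metric_frames, ignore_index=True)
               if metric_frames else pd.DataFrame())
    fixations = (pd.concat(fix_frames, ignore_index=True)
                 if fix_frames else pd.DataFrame())

    model = None
    records = pd.DataFrame()
    if fit_model and len(metrics):
        records = build_model_table(metrics, dataset["ratings"], participants,
                                    config.covariate)
        model = run_analysis(records, config.covariate)

    manifest = RunManifest(
        config_hash=config.config_hash(), version=__version__,
        n_participants_in=len(dataset["streams"]),
        n_participants_kept=int(qc_parts["keep"].sum()) if len(qc_parts) else 0,
        n_trials_in=int(sum(len(v) for v in all_decisions.values())),
        n_trials_valid=int(qc_trials["valid"].sum()) if len(qc_trials) else 0,
        exclusion_tally=dict(sorted(tally.items())),
        wall_time_s=round(time.perf_counter() - t0, 3))
    return PipelineResult(manifest, qc_trials, qc_parts, fixations, metrics,
                          records, model)


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write every pipeline table plus the manifest to ``outdir``."""
    from .io import write_table
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(result.qc_trials, out / "qc_trials.csv")
    write_table(result.qc_participants, out / "qc_participants.csv")
    write_table(result.fixations, out / "fixations.csv")
    write_table(result.metrics, out / "metrics.csv")
    if result.model is not None:
        write_table(result.model.table(), out / "results.csv")
        write_table(result.model.candidates, out / "candidates.csv")
    (out / "manifest.json").write_text(result.manifest.to_json())
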