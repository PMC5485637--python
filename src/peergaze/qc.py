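"""Trial segmentation, trial/participant exclusion rules, calibration QC.

Exclusion rules (applied to the *pre-repair* validity mask):

i)   more than 1000 ms of consecutive invalid samples anywhere after
     fixation-cross onset,
ii)  more than 1000 ms of consecutive invalid samples between fixation onset
     and scene offset,
iii) more than 40% invalid samples between fixation onset and scene offset.

Boundary semantics are strict exactly as worded: a run of exactly 1000 ms is
retained; a participant with exactly 30 valid trials per perspective
condition is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, deg_to_px
from .stream import GazeStream

logger = logging.getLogger(__name__)

__all__ = [
    "TrialWindow",
    "TrialSegment",
    "QCDecision",
    "QCConfig",
    "CalibrationResult",
    "segment_trials",
    "longest_invalid_run",
    "qc_trial",
    "qc_participant",
    "calibration_qc",
]

EVENT_NAMES = ("fixation_onset", "scene_onset", "scene_offset",
               "statement_offset", "rating")


@dataclass(frozen=True)
class TrialWindow:
    trial_id: str
    fixation_onset_ms: float
    scene_onset_ms: float
    scene_offset_ms: float
    statement_offset_ms: float
    rating_ms: float
    perspective: str | None = None
    valence: str | None = None
    scene_id: int | None = None

    def __post_init__(self) -> None:
        ts = (self.fixation_onset_ms, self.scene_onset_ms, self.scene_offset_ms,
              self.statement_offset_ms, self.rating_ms)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"trial {self.trial_id}: markers must be strictly ordered")


@dataclass
class TrialSegment:
    window: TrialWindow
    stream: GazeStream
    #: index of the segment's first sample in the parent stream
    start_index: int = 0


@dataclass(frozen=True)
class QCConfig:
    max_invalid_run_ms: float = 1000.0
    max_invalid_fraction: float = 0.40
    min_valid_trials_per_condition: int = 30
    condition_column: str = "perspective"


@dataclass(frozen=True)
class QCDecision:
    trial_id: str
    valid: bool
    reasons: tuple[str, ...]
    invalid_fraction: float
    longest_run_after_fix_ms: float
    longest_run_before_offset_ms: float

    def __post_init__(self) -> None:
        if self.valid != (len(self.reasons) == 0):
            raise ValueError("valid must be True iff reasons is empty")


def segment_trials(stream: GazeStream, events: pd.DataFrame,
                   design: pd.DataFrame | None = None) -> list[TrialSegment]:
    """Cut a continuous stream into per-trial segments.

    ``events`` needs columns trial_id, event, t_ms with one row per marker.
    Trials missing any of the five markers are dropped (logged).  Each
    segment spans [fixation_onset, rating] inclusive.
    """
    segments: list[TrialSegment] = []
    cond: dict = {}
    if design is not None:
        cond = {str(r.trial_id): r for r in design.itertuples(index=False)}
    for trial_id, grp in events.groupby("trial_id", sort=False):
        marks = dict(zip(grp["event"], grp["t_ms"]))
        missing = [e for e in EVENT_NAMES if e not in marks]
        if missing:
            logger.warning("trial %s dropped: missing markers %s", trial_id, missing)
            continue
        info = cond.get(str(trial_id))
        try:
            win = TrialWindow(
                trial_id=str(trial_id),
                fixation_onset_ms=float(marks["fixation_onset"]),
                scene_onset_ms=float(marks["scene_onset"]),
                scene_offset_ms=float(marks["scene_offset"]),
                statement_offset_ms=float(marks["statement_offset"]),
                rating_ms=float(marks["rating"]),
                perspective=getattr(info, "perspective", None),
                valence=getattr(info, "valence", None),
                scene_id=int(info.scene_id) if info is not None else None,
            )
        except ValueError as err:
            logger.warning("trial %s dropped: %s", trial_id, err)
            continue
        i0, i1 = stream.window_indices(win.fixation_onset_ms, win.rating_ms)
        i1 = min(i1 + 1, stream.n)  # include the sample at the rating mark
        if i1 <= i0:
            logger.warning("trial %s dropped: no samples in window", trial_id)
            continue
        segments.append(TrialSegment(win, stream.slice(i0, i1), start_index=i0))
    return segments


def longest_invalid_run(mask: np.ndarray, window: tuple[int, int],
                        rate_hz: float) -> float:
    """Longest contiguous run of invalid samples inside ``[i0, i1)``, in ms."""
    i0, i1 = window
    if i1 <= i0:
        raise ValueError("empty QC window")
    invalid = ~np.asarray(mask[i0:i1], dtype=bool)
    if not invalid.any():
        return 0.0
    padded = np.concatenate(([False], invalid, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    run_lengths = edges[1::2] - edges[0::2]
    return float(run_lengths.max()) * 1000.0 / rate_hz


def qc_trial(segment: TrialSegment, mask: np.ndarray,
             config: QCConfig = QCConfig(),
             drift_uncorrectable: bool = False) -> QCDecision:
    """Apply the three invalid-data rules to one trial.

    ``mask`` is the pre-repair validity mask aligned with ``segment.stream``.
    """
    st = segment.stream
    win = segment.window
    rate = st.rate_hz
    n = st.n
    j_off, _ = st.window_indices(win.scene_offset_ms, win.scene_offset_ms)
    j_off = min(max(j_off, 1), n)

    run_all = longest_invalid_run(mask, (0, n), rate)
    run_pre = longest_invalid_run(mask, (0, j_off), rate)
    frac = float(np.mean(~np.asarray(mask[:j_off], bool)))

    reasons: list[str] = []
    eps = 1e-6  # guard against float rounding of sample periods at the boundary
    if run_all > config.max_invalid_run_ms + eps:
        reasons.append("run_after_fix_onset")
    if run_pre > config.max_invalid_run_ms + eps:
        reasons.append("run_before_scene_offset")
    if frac > config.max_invalid_fraction:
        reasons.append("pct_invalid")
    if drift_uncorrectable:
        reasons.append("drift_uncorrectable")
    return QCDecision(win.trial_id, not reasons, tuple(reasons), frac,
                      run_all, run_pre)


def qc_participant(decisions: list[QCDecision], design: pd.DataFrame,
                   config: QCConfig = QCConfig()) -> tuple[bool, dict[str, int]]:
    """Keep a participant iff every condition has enough valid trials.

    ``design`` must carry trial_id and the condition column (perspective by
    default: self/other).
    """
    valid_ids = {d.trial_id for d in decisions if d.valid}
    col = config.condition_column
    counts: dict[str, int] = {}
    if len(design) == 0 or col not in design.columns:
        return False, counts
    for level, grp in design.groupby(col):
        counts[str(level)] = int(grp["trial_id"].astype(str).isin(valid_ids).sum())
    keep = bool(counts) and all(
        c >= config.min_valid_trials_per_condition for c in counts.values())
    return keep, counts


@dataclass(frozen=True)
class CalibrationResult:
    samples_within_1deg: tuple[int, ...]
    passed: bool
    min_required: int = 12


def calibration_qc(samples_per_point: list[np.ndarray],
                   targets_px: np.ndarray, geometry: ScreenGeometry,
                   min_samples: int = 12, radius_deg: float = 1.0,
                   ) -> CalibrationResult:
    """Nine-point calibration check: per point, count gaze samples within
    1 degree of the target; pass iff every count reaches the minimum."""
    targets_px = np.asarray(targets_px, dtype=float)
    if targets_px.shape != (9, 2) or len(samples_per_point) != 9:
        raise ValueError("calibration uses exactly 9 points")
    radius_px = deg_to_px(radius_deg, geometry)
    counts = []
    for pts, tgt in zip(samples_per_point, targets_px):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        if pts.size == 0:
            counts.append(0)
            continue
        d = np.hypot(pts[:, 0] - tgt[0], pts[:, 1] - tgt[1])
        counts.append(int(np.sum(d <= radius_px)))
    passed = all(c >= min_samples for c in counts)
    return CalibrationResult(tuple(counts), passed, min_samples)
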