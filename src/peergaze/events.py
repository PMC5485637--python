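"""Fixation detection and AOI dwell-time metrics.

The detector is a velocity-dispersion-duration hybrid:

* candidate samples have gaze speed below 75 deg/s (central difference over
  two samples of the smoothed analysis-eye gaze);
* contiguous candidate runs are scanned left to right with a running
  centroid; the fixation is closed at the previous sample whenever the
  incoming sample would sit more than 2 deg from the updated centroid;
* groups shorter than 75 ms are discarded.

Dwell time on the peer-face areas of interest (AOIs) is the summed duration
of fixations whose centroid falls inside any AOI rectangle, clipped to the
5 s free-viewing window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, deg_per_px, scene_rect_px

__all__ = [
    "FixationParams",
    "Fixation",
    "TrialMetrics",
    "compute_velocity",
    "detect_fixations",
    "aoi_fixation_time",
    "condition_summary",
]


@dataclass(frozen=True)
class FixationParams:
    velocity_threshold_deg_s: float = 75.0
    dispersion_threshold_deg: float = 2.0
    min_duration_ms: float = 75.0
    #: 'centroid' assigns a fixation to an AOI by its centroid;
    #: 'sample' weighs per-sample membership instead.
    aoi_assignment: str = "centroid"

    def __post_init__(self) -> None:
        if min(self.velocity_threshold_deg_s, self.dispersion_threshold_deg,
               self.min_duration_ms) <= 0:
            raise ValueError("fixation parameters must be positive")
        if self.aoi_assignment not in ("centroid", "sample"):
            raise ValueError("aoi_assignment must be 'centroid' or 'sample'")


@dataclass(frozen=True)
class Fixation:
    onset_ms: float
    offset_ms: float
    centroid_px: tuple[float, float]
    n_samples: int
    max_dispersion_deg: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class TrialMetrics:
    trial_id: str
    total_aoi_fixation_ms: float
    n_fixations: int
    perspective: str | None = None
    valence: str | None = None
    scene_id: int | None = None


def compute_velocity(t_ms: np.ndarray, x_px: np.ndarray, y_px: np.ndarray,
                     geometry: ScreenGeometry) -> np.ndarray:
    """Gaze speed in degrees per second.

    Central difference over two samples on interior points, one-sided at the
    two endpoints.
    """
    n = len(t_ms)
    if n < 3:
        raise ValueError("need >= 3 samples to compute velocity")
    k = deg_per_px(geometry)
    v = np.empty(n)
    dt = (t_ms[2:] - t_ms[:-2]) / 1000.0
    v[1:-1] = np.hypot(x_px[2:] - x_px[:-2], y_px[2:] - y_px[:-2]) * k / dt
    v[0] = np.hypot(x_px[1] - x_px[0], y_px[1] - y_px[0]) * k / ((t_ms[1] - t_ms[0]) / 1000.0)
    v[-1] = np.hypot(x_px[-1] - x_px[-2], y_px[-1] - y_px[-2]) * k / ((t_ms[-1] - t_ms[-2]) / 1000.0)
    return v


def detect_fixations(t_ms: np.ndarray, x_px: np.ndarray, y_px: np.ndarray,
                     params: FixationParams, geometry: ScreenGeometry,
                     velocity: np.ndarray | None = None) -> list[Fixation]:
    """Velocity-dispersion-duration fixation detection on one trial slice."""
    t_ms = np.asarray(t_ms, float)
    x_px = np.asarray(x_px, float)
    y_px = np.asarray(y_px, float)
    if velocity is None:
        velocity = compute_velocity(t_ms, x_px, y_px, geometry)
    candidate = velocity < params.velocity_threshold_deg_s
    disp_px = params.dispersion_threshold_deg / deg_per_px(geometry)

    fixations: list[Fixation] = []
    padded = np.concatenate(([False], candidate, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for r0, r1 in zip(edges[0::2], edges[1::2]):
        start = int(r0)
        sx = sy = 0.0
        cnt = 0
        for j in range(int(r0), int(r1)):
            nx, ny = sx + x_px[j], sy + y_px[j]
            cx, cy = nx / (cnt + 1), ny / (cnt + 1)
            if cnt > 0 and np.hypot(x_px[j] - cx, y_px[j] - cy) > disp_px:
                _close_group(fixations, t_ms, x_px, y_px, start, j, params, disp_px,
                             geometry)
                start, sx, sy, cnt = j, x_px[j], y_px[j], 1
            else:
                sx, sy, cnt = nx, ny, cnt + 1
        _close_group(fixations, t_ms, x_px, y_px, start, int(r1), params, disp_px,
                     geometry)
    return fixations


def _close_group(out: list[Fixation], t_ms, x_px, y_px, i0: int, i1: int,
                 params: FixationParams, disp_px: float,
                 geometry: ScreenGeometry) -> None:
    if i1 - i0 < 2:
        return
    dur = float(t_ms[i1 - 1] - t_ms[i0])
    if dur < params.min_duration_ms:
        return
    cx = float(np.mean(x_px[i0:i1]))
    cy = float(np.mean(y_px[i0:i1]))
    disp = float(np.max(np.hypot(x_px[i0:i1] - cx, y_px[i0:i1] - cy)))
    out.append(Fixation(float(t_ms[i0]), float(t_ms[i1 - 1]), (cx, cy),
                        i1 - i0, disp * deg_per_px(geometry)))


def _point_in_rects(x: float, y: float, rects: list[tuple[float, float, float, float]],
                    origin: tuple[float, float]) -> bool:
    ox, oy = origin
    for rx, ry, rw, rh in rects:
        if ox + rx <= x < ox + rx + rw and oy + ry <= y < oy + ry + rh:
            return True
    return False


def aoi_fixation_time(fixations: list[Fixation],
                      aoi_set: dict[int, list[tuple[float, float, float, float]]],
                      scene_id: int, scene_window_ms: tuple[float, float],
                      geometry: ScreenGeometry,
                      trial_id: str = "", perspective: str | None = None,
                      valence: str | None = None) -> TrialMetrics:
    """Total fixation time on the scene's peer-face AOIs inside the viewing
    window.

    AOI rectangles are given in scene pixels; they are shifted by the scene's
    on-screen origin before testing fixation centroids.  A fixation straddling
    the window boundary contributes only its in-window portion.
    """
    if scene_id not in aoi_set:
        raise KeyError(f"unknown scene_id {scene_id}")
    rects = [tuple(map(float, r)) for r in aoi_set[scene_id]]
    origin = scene_rect_px(geometry)[:2]
    w0, w1 = scene_window_ms
    total = 0.0
    n_fix = 0
    for f in fixations:
        a, b = max(f.onset_ms, w0), min(f.offset_ms, w1)
        if b <= a:
            continue
        n_fix += 1
        if _point_in_rects(f.centroid_px[0], f.centroid_px[1], rects, origin):
            total += b - a
    total = min(total, w1 - w0)
    return TrialMetrics(trial_id, total, n_fix, perspective, valence, scene_id)


def condition_summary(metrics: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-condition mean AOI dwell times.

    ``metrics`` has one row per trial (trial_id, total_aoi_fixation_ms);
    ``design`` supplies participant_id, perspective and valence per trial_id.
    """
    joined = metrics.merge(
        design[["trial_id", "participant_id", "perspective", "valence"]],
        on="trial_id", how="left", suffixes=("", "_design"))
    for col in ("perspective", "valence"):
        if col not in joined or joined[col].isna().all():
            joined[col] = joined[f"{col}_design"]
    out = (joined.groupby(["participant_id", "perspective", "valence"],
                          as_index=False)["total_aoi_fixation_ms"]
           .mean()
           .rename(columns={"total_aoi_fixation_ms": "mean_aoi_fixation_ms"}))
    return out
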