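"""Signal cleaning for 300 Hz binocular gaze recordings.

The cleaning chain mirrors standard desktop eye-tracking practice:

1. validity flagging (tracker flag, on-screen gaze, physiological pupil),
2. Savitzky-Golay smoothing of gaze (order 2, 7 samples) and a 3-sample
   running median on pupil diameter,
3. blink detection from the instantaneous rate of change of pupil diameter
   (> 0.1 mm per sample in *both* eyes),
4. repair of invalid samples (zero-order hold for gaze, linear interpolation
   for pupil),
5. pupil baseline correction against the 200 ms before scene onset,
6. per-trial drift correction against the fixation cross (applied only when
   the required shift is below 150 px), with an optional participant-level
   vertical correction for recordings with a global y bias.

Every function returns new arrays/streams; inputs are never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .geometry import ScreenGeometry
from .stream import GazeStream

__all__ = [
    "CleaningConfig",
    "DriftResult",
    "flag_validity",
    "smooth_gaze",
    "smooth_pupil",
    "detect_blinks",
    "blink_mask",
    "repair_invalid",
    "baseline_correct_pupil",
    "drift_correct_trial",
    "participant_y_correction",
]


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds and filter settings of the cleaning chain.

    ``blink_rate_threshold_mm`` is the per-sample absolute change in pupil
    diameter (mm/sample at the nominal rate) above which, in both eyes
    simultaneously, samples are treated as blink artifact.
    """

    sg_order: int = 2
    sg_window_samples: int = 7
    pupil_median_window_samples: int = 3
    baseline_window_ms: float = 200.0
    blink_rate_threshold_mm: float = 0.1
    pupil_physiological_range_mm: tuple[float, float] = (1.5, 9.0)
    analysis_eye: str = "left"
    drift_max_offset_px: float = 150.0
    drift_per_axis: bool = False
    y_correction_threshold_px: float = 30.0

    def __post_init__(self) -> None:
        if self.sg_window_samples % 2 == 0 or self.sg_window_samples <= self.sg_order:
            raise ValueError("sg_window_samples must be odd and > sg_order")
        if self.pupil_median_window_samples % 2 == 0:
            raise ValueError("pupil_median_window_samples must be odd")
        for v in (self.baseline_window_ms, self.blink_rate_threshold_mm,
                  self.drift_max_offset_px):
            if v <= 0:
                raise ValueError("thresholds must be positive")
        lo, hi = self.pupil_physiological_range_mm
        if not 0 < lo < hi:
            raise ValueError("pupil range must satisfy 0 < lo < hi")


def flag_validity(stream: GazeStream, geometry: ScreenGeometry,
                  config: CleaningConfig) -> np.ndarray:
    """Per-sample validity mask; the stream itself is untouched.

    A sample is valid iff, for both eyes: the tracker found the eye, gaze
    falls inside the screen area, and pupil diameter is positive and within
    the physiological range.
    """
    w, h = geometry.screen_px
    lo, hi = config.pupil_physiological_range_mm
    on_screen = (
        (stream.lx >= 0) & (stream.lx < w) & (stream.ly >= 0) & (stream.ly < h)
        & (stream.rx >= 0) & (stream.rx < w) & (stream.ry >= 0) & (stream.ry < h)
    )
    pupil_ok = (
        (stream.lpupil > 0) & (stream.lpupil >= lo) & (stream.lpupil <= hi)
        & (stream.rpupil > 0) & (stream.rpupil >= lo) & (stream.rpupil <= hi)
    )
    return np.asarray(stream.tracker_valid, dtype=bool) & on_screen & pupil_ok


def smooth_gaze(stream: GazeStream, config: CleaningConfig) -> GazeStream:
    """Savitzky-Golay smoothing of all four gaze channels.

    Edges use a polynomial fit over the truncated terminal window
    (scipy's ``mode='interp'``).
    """
    if stream.n < config.sg_window_samples:
        raise ValueError(
            f"need >= {config.sg_window_samples} samples, got {stream.n}")
    out = stream.copy()
    for name in ("lx", "ly", "rx", "ry"):
        setattr(out, name, savgol_filter(
            getattr(stream, name), config.sg_window_samples, config.sg_order,
            mode="interp"))
    return out


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Odd-window running median; the half-window edges pass through."""
    n = len(x)
    half = window // 2
    out = np.array(x, dtype=float, copy=True)
    if n < window:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(x, window)
    out[half:n - half] = np.median(windows, axis=1)
    return out


def smooth_pupil(stream: GazeStream, config: CleaningConfig) -> GazeStream:
    if stream.n < config.pupil_median_window_samples:
        raise ValueError("too few samples for the pupil median filter")
    out = stream.copy()
    out.lpupil = _running_median(stream.lpupil, config.pupil_median_window_samples)
    out.rpupil = _running_median(stream.rpupil, config.pupil_median_window_samples)
    return out


def detect_blinks(stream: GazeStream, config: CleaningConfig) -> list[tuple[int, int]]:
    """Blink sections as half-open sample-index intervals ``[start, stop)``.

    A sample belongs to a blink section when the absolute first difference of
    (smoothed) pupil diameter exceeds the threshold in both eyes; sections are
    the maximal contiguous runs of such samples.
    """
    if stream.n < 2:
        return []
    thr = config.blink_rate_threshold_mm
    dl = np.abs(np.diff(stream.lpupil, prepend=stream.lpupil[0]))
    dr = np.abs(np.diff(stream.rpupil, prepend=stream.rpupil[0]))
    supra = (dl > thr) & (dr > thr)
    return _runs_of_true(supra)


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], np.asarray(mask, bool), [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def blink_mask(stream: GazeStream, sections: list[tuple[int, int]]) -> np.ndarray:
    """Boolean array marking samples inside blink sections."""
    m = np.zeros(stream.n, dtype=bool)
    for a, b in sections:
        m[a:b] = True
    return m


def repair_invalid(stream: GazeStream, mask: np.ndarray) -> GazeStream:
    """Replace invalid samples: gaze by zero-order hold, pupil by linear
    interpolation.

    ``mask`` is True for valid samples.  Leading invalid gaze samples take the
    first valid value; pupil extrapolation at either end is by nearest valid
    value.  Valid samples are returned unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (stream.n,):
        raise ValueError("mask length must equal sample count")
    if not mask.any():
        raise ValueError("cannot repair a stream with no valid samples")
    out = stream.copy()
    valid_idx = np.flatnonzero(mask)
    # gaze: index of the last valid sample at or before each position
    pos = np.arange(stream.n)
    last = np.searchsorted(valid_idx, pos, side="right") - 1
    src = valid_idx[np.clip(last, 0, None)]  # leading invalids -> first valid
    for name in ("lx", "ly", "rx", "ry"):
        setattr(out, name, getattr(stream, name)[src])
    # pupil: linear interpolation between flanking valid samples
    t = stream.t_ms
    for name in ("lpupil", "rpupil"):
        p = getattr(stream, name)
        setattr(out, name, np.interp(t, t[valid_idx], p[valid_idx]))
    return out


def baseline_correct_pupil(stream: GazeStream, scene_onset_ms: float,
                           config: CleaningConfig) -> GazeStream:
    """Subtract the mean pupil diameter over the window before scene onset."""
    t0 = scene_onset_ms - config.baseline_window_ms
    if stream.t_ms[0] > t0:
        raise ValueError(
            f"need {config.baseline_window_ms:g} ms of data before scene onset")
    i0, i1 = stream.window_indices(t0, scene_onset_ms)
    if i1 <= i0:
        raise ValueError("empty baseline window")
    out = stream.copy()
    out.lpupil = stream.lpupil - float(np.mean(stream.lpupil[i0:i1]))
    out.rpupil = stream.rpupil - float(np.mean(stream.rpupil[i0:i1]))
    return out


@dataclass(frozen=True)
class DriftResult:
    applied: bool
    offset_px: tuple[float, float] | None
    reason: str | None = None


def drift_correct_trial(stream: GazeStream, cross_position_px: tuple[float, float],
                        fixation_window_ms: tuple[float, float],
                        config: CleaningConfig,
                        validity: np.ndarray | None = None,
                        ) -> tuple[GazeStream, DriftResult]:
    """Per-trial constant drift correction against the fixation cross.

    The offset is the cross position minus the per-axis median of valid
    analysis-eye gaze during the cross window.  It is added to all gaze
    samples (both eyes) only when its magnitude is below the configured
    limit; otherwise the stream is returned unchanged.
    """
    i0, i1 = stream.window_indices(*fixation_window_ms)
    gx, gy = stream.eye(config.analysis_eye)
    sel = np.ones(stream.n, dtype=bool) if validity is None else np.asarray(validity, bool)
    win = sel[i0:i1]
    if i1 <= i0 or not win.any():
        return stream, DriftResult(False, None, "no_valid_cross_samples")
    ox = cross_position_px[0] - float(np.median(gx[i0:i1][win]))
    oy = cross_position_px[1] - float(np.median(gy[i0:i1][win]))
    if config.drift_per_axis:
        too_big = max(abs(ox), abs(oy)) >= config.drift_max_offset_px
    else:
        too_big = float(np.hypot(ox, oy)) >= config.drift_max_offset_px
    if too_big:
        return stream, DriftResult(False, (ox, oy), "offset_too_large")
    out = stream.copy()
    out.lx = stream.lx + ox
    out.rx = stream.rx + ox
    out.ly = stream.ly + oy
    out.ry = stream.ry + oy
    return out, DriftResult(True, (ox, oy))


def participant_y_correction(
    trials: list[GazeStream],
    cross_position_px: tuple[float, float],
    fixation_windows_ms: list[tuple[float, float]],
    config: CleaningConfig,
    validities: list[np.ndarray] | None = None,
) -> tuple[list[GazeStream], float]:
    """Participant-level vertical gaze correction.

    Some recordings carry a constant vertical bias (e.g. a headrest slightly
    off the calibrated position).  The per-trial vertical cross offsets are
    pooled; when their participant-level median exceeds the trigger threshold
    it is applied to every trial's y channels before per-trial drift
    correction.  Returns the (possibly corrected) trials and the shift that
    was applied (0.0 when none).
    """
    offsets = []
    for k, (st, win) in enumerate(zip(trials, fixation_windows_ms)):
        i0, i1 = st.window_indices(*win)
        sel = np.ones(st.n, bool) if validities is None else np.asarray(validities[k], bool)
        w = sel[i0:i1]
        if i1 > i0 and w.any():
            _, gy = st.eye(config.analysis_eye)
            offsets.append(cross_position_px[1] - float(np.median(gy[i0:i1][w])))
    if not offsets:
        return [t.copy() for t in trials], 0.0
    bias = float(np.median(offsets))
    if abs(bias) <= config.y_correction_threshold_px:
        return [t.copy() for t in trials], 0.0
    out = []
    for st in trials:
        c = st.copy()
        c.ly = st.ly + bias
        c.ry = st.ry + bias
        out.append(c)
    return out, bias
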