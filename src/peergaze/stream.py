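"""The binocular gaze stream container.

A :class:`GazeStream` holds uniformly sampled binocular gaze (screen pixels),
pupil diameter (mm) and the tracker's per-sample found-both-eyes flag.  All
signal operations take and return streams; none mutates its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GazeStream"]


@dataclass
class GazeStream:
    t_ms: np.ndarray
    lx: np.ndarray
    ly: np.ndarray
    rx: np.ndarray
    ry: np.ndarray
    lpupil: np.ndarray
    rpupil: np.ndarray
    tracker_valid: np.ndarray

    def __post_init__(self) -> None:
        arrs = [self.t_ms, self.lx, self.ly, self.rx, self.ry,
                self.lpupil, self.rpupil, self.tracker_valid]
        n = len(self.t_ms)
        if any(len(a) != n for a in arrs):
            raise ValueError("all channels must have equal length")
        if n >= 2 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def n(self) -> int:
        return len(self.t_ms)

    @property
    def sample_period_ms(self) -> float:
        if len(self.t_ms) < 2:
            raise ValueError("need >= 2 samples to infer the sample period")
        return float(np.median(np.diff(self.t_ms)))

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.sample_period_ms

    def eye(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Gaze (x, y) arrays for the requested eye ('left' or 'right')."""
        if which == "left":
            return self.lx, self.ly
        if which == "right":
            return self.rx, self.ry
        raise ValueError(f"unknown eye {which!r}")

    def pupil(self, which: str) -> np.ndarray:
        if which == "left":
            return self.lpupil
        if which == "right":
            return self.rpupil
        raise ValueError(f"unknown eye {which!r}")

    def copy(self) -> "GazeStream":
        return GazeStream(*(np.array(a, copy=True) for a in (
            self.t_ms, self.lx, self.ly, self.rx, self.ry,
            self.lpupil, self.rpupil, self.tracker_valid)))

    def slice(self, i0: int, i1: int) -> "GazeStream":
        """Sample-index slice [i0, i1) as a new stream (views copied)."""
        return GazeStream(*(np.array(a[i0:i1], copy=True) for a in (
            self.t_ms, self.lx, self.ly, self.rx, self.ry,
            self.lpupil, self.rpupil, self.tracker_valid)))

    def window_indices(self, t0_ms: float, t1_ms: float) -> tuple[int, int]:
        """Index range [i0, i1) of samples with t0 <= t < t1."""
        i0 = int(np.searchsorted(self.t_ms, t0_ms, side="left"))
        i1 = int(np.searchsorted(self.t_ms, t1_ms, side="left"))
        return i0, i1
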