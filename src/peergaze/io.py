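"""Readers/writers for the pipeline's plain-text artifact files.

Dataset directory layout (as written by ``peergaze simulate``):

    design.csv          one row per trial (participant, scene, conditions)
    participants.csv    questionnaire items + age per participant
    aois.json           scene_id -> [{x, y, w, h}, ...] in scene pixels
    ratings.csv         trial_id, rating
    gaze_<pid>.csv      t_ms, lx_px, ly_px, rx_px, ry_px, lpupil_mm,
                        rpupil_mm, valid_flag
    events_<pid>.csv    participant_id, trial_id, event, t_ms
    truth.json          ground-truth sidecar (events, model, dwell times)

All readers are header-driven (column order does not matter) and validate
what the containers require; round trips preserve values to full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .stream import GazeStream

__all__ = [
    "GAZE_COLUMNS",
    "read_gaze_csv", "write_gaze_csv",
    "read_events_csv", "write_events_csv",
    "read_aoi_json", "write_aoi_json",
    "read_table", "write_table",
    "write_dataset", "read_dataset_dir",
]

GAZE_COLUMNS = ("t_ms", "lx_px", "ly_px", "rx_px", "ry_px",
                "lpupil_mm", "rpupil_mm", "valid_flag")
_FLOAT_FMT = "%.10g"


def read_gaze_csv(path: str | Path) -> GazeStream:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[list(GAZE_COLUMNS)].isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{path}: malformed row at line {line}")
    return GazeStream(
        df["t_ms"].to_numpy(float), df["lx_px"].to_numpy(float),
        df["ly_px"].to_numpy(float), df["rx_px"].to_numpy(float),
        df["ry_px"].to_numpy(float), df["lpupil_mm"].to_numpy(float),
        df["rpupil_mm"].to_numpy(float),
        df["valid_flag"].to_numpy(int).astype(bool))


def write_gaze_csv(stream: GazeStream, path: str | Path) -> None:
    df = pd.DataFrame({
        "t_ms": stream.t_ms, "lx_px": stream.lx, "ly_px": stream.ly,
        "rx_px": stream.rx, "ry_px": stream.ry,
        "lpupil_mm": stream.lpupil, "rpupil_mm": stream.rpupil,
        "valid_flag": stream.tracker_valid.astype(int)})
    df.to_csv(path, index=False, float_format="%.17g")


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("trial_id", "event", "t_ms"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    return df


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False, float_format="%.17g")


def read_aoi_json(path: str | Path) -> dict[int, list[tuple[float, float, float, float]]]:
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): [(float(r["x"]), float(r["y"]), float(r["w"]), float(r["h"]))
                     for r in v] for k, v in raw.items()}


def write_aoi_json(aois: dict[int, list[tuple[float, float, float, float]]],
                   path: str | Path) -> None:
    raw = {str(k): [{"x": r[0], "y": r[1], "w": r[2], "h": r[3]} for r in v]
           for k, v in aois.items()}
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1, sort_keys=True)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def write_dataset(dataset, outdir: str | Path) -> None:
    """Write a :class:`~peergaze.simulate.SimulatedDataset` to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(dataset.design, out / "design.csv")
    write_table(dataset.participants, out / "participants.csv")
    write_table(dataset.ratings, out / "ratings.csv")
    write_aoi_json(dataset.aois, out / "aois.json")
    for pid, stream in dataset.streams.items():
        write_gaze_csv(stream, out / f"gaze_{pid}.csv")
        ev = dataset.events[dataset.events["participant_id"] == pid]
        write_events_csv(ev, out / f"events_{pid}.csv")
    truth = {
        "model": {"beta": dataset.truth_model.beta,
                  "sigma_subject": dataset.truth_model.sigma_subject,
                  "sigma_scene": dataset.truth_model.sigma_scene,
                  "sigma_resid": dataset.truth_model.sigma_resid},
        "true_aoi_fixation_ms": {
            r.trial_id: r.true_aoi_fixation_ms
            for r in dataset.true_fixation_time_ms.itertuples(index=False)},
        "events": {tid: [{"kind": e.kind, "onset_ms": e.onset_ms,
                          "offset_ms": e.offset_ms,
                          "centroid_px": e.centroid_px}
                         for e in evs]
                   for tid, evs in dataset.truth_events.items()},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh)


def read_dataset_dir(path: str | Path) -> dict:
    """Load a dataset directory into in-memory tables and streams."""
    p = Path(path)
    for required in ("design.csv", "participants.csv", "ratings.csv", "aois.json"):
        if not (p / required).exists():
            raise FileNotFoundError(f"dataset file missing: {p / required}")
    design = read_table(p / "design.csv")
    streams: dict[str, GazeStream] = {}
    events_frames = []
    for pid in sorted(design["participant_id"].unique()):
        gaze_path = p / f"gaze_{pid}.csv"
        ev_path = p / f"events_{pid}.csv"
        if not gaze_path.exists():
            raise FileNotFoundError(f"dataset file missing: {gaze_path}")
        if not ev_path.exists():
            raise FileNotFoundError(f"dataset file missing: {ev_path}")
        streams[pid] = read_gaze_csv(gaze_path)
        events_frames.append(read_events_csv(ev_path))
    return {
        "design": design,
        "participants": read_table(p / "participants.csv"),
        "ratings": read_table(p / "ratings.csv"),
        "aois": read_aoi_json(p / "aois.json"),
        "streams": streams,
        "events": pd.concat(events_frames, ignore_index=True),
    }
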