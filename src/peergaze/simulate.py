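"""Synthetic study generator: designs, gaze streams, questionnaires, ratings.

The generator emulates the free-viewing peer-scene interpretation task so the
whole pipeline can be exercised against known ground truth:

* a counterbalanced design of 72 scenes x {self, other} x {positive,
  negative} statements in 6 blocks of 12 trials;
* 300 Hz binocular gaze with scripted or random fixation/saccade/blink
  sequences, AR(1) oculomotor + tracker noise specified in degrees, per-trial
  drift offsets and optional participant-level vertical bias;
* SAS-A / PDS item responses and ages;
* interpretation ratings drawn from a known crossed random-intercepts linear
  model (the :class:`TruthModel`), truncated to the 0-100 rating scale.

Every function is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, deg_to_px, scene_center_px, scene_rect_px
from .stream import GazeStream
from . import inference as _inf

__all__ = [
    "SimulationConfig",
    "TruthModel",
    "GroundTruthEvent",
    "TrialSpec",
    "SimulatedDataset",
    "default_truth",
    "generate_design",
    "generate_aois",
    "simulate_participants",
    "simulate_gaze_trial",
    "simulate_ratings",
    "simulate_dataset",
    "true_aoi_fixation_time",
]

N_SCENES = 72
N_BLOCKS = 6
TRIALS_PER_BLOCK = 12


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated experiment.

    Trial timing follows the task: fixation cross jittered 1-2 s, scene alone
    for 5 s, scene + statement for 3 s, rating thereafter, inter-trial
    interval jittered 5-6 s.  Gaze noise is an isotropic AR(1) Gaussian
    process specified in degrees; ``noise_ar1_rho`` = 0.99 at 300 Hz
    reproduces the ~0.05 deg RMS sample-to-sample precision of research-grade
    video trackers while keeping the marginal dispersion at ``noise_sd_deg``.
    """

    n_participants: int = 10
    seed: int = 0
    sampling_rate_hz: float = 300.0
    noise_sd_deg: float = 0.3
    noise_ar1_rho: float = 0.99
    fixation_duration_ms: tuple[float, float] = (200.0, 800.0)
    saccade_duration_ms: tuple[float, float] = (20.0, 60.0)
    saccade_ms_per_deg: float = 4.0
    min_target_separation_deg: float = 4.0
    p_fixation_on_aoi: float = 0.45
    blink_probability: float = 0.25
    blink_duration_ms: tuple[float, float] = (100.0, 300.0)
    drift_offset_sd_px: float = 20.0
    y_bias_px: float = 0.0
    validity_noise_rate: float = 0.0
    cross_duration_ms: tuple[float, float] = (1000.0, 2000.0)
    scene_duration_ms: float = 5000.0
    statement_duration_ms: float = 3000.0
    rating_latency_ms: tuple[float, float] = (500.0, 2500.0)
    iti_ms: tuple[float, float] = (5000.0, 6000.0)
    pupil_base_mm: tuple[float, float] = (3.5, 4.5)
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)

    def __post_init__(self) -> None:
        for lo_hi in (self.fixation_duration_ms, self.saccade_duration_ms,
                      self.blink_duration_ms, self.cross_duration_ms,
                      self.rating_latency_ms, self.iti_ms):
            if lo_hi[0] <= 0 or lo_hi[1] < lo_hi[0]:
                raise ValueError("duration ranges must be positive and ordered")
        if self.scene_duration_ms <= 0 or self.statement_duration_ms <= 0:
            raise ValueError("durations must be positive")
        if not 0 <= self.blink_probability <= 1:
            raise ValueError("blink_probability must be in [0, 1]")


@dataclass(frozen=True)
class TruthModel:
    """Generative fixed-effect coefficients (0-100 rating scale) and random
    standard deviations for subject, scene and residual."""

    beta: dict[str, float]
    sigma_subject: float
    sigma_scene: float
    sigma_resid: float

    def __post_init__(self) -> None:
        if min(self.sigma_subject, self.sigma_scene, self.sigma_resid) < 0:
            raise ValueError("sigmas must be non-negative")


def default_truth(which: str = "anxiety") -> TruthModel:
    """Recovery-harness truth with effects at the magnitude the method is
    designed to detect (intercept ~50, key interactions of ~4-5 rating units;
    subject/scene/residual sd 6/4/20)."""
    if which == "anxiety":
        beta = {"intercept": 50.0, "anxiety": 2.9,
                "perspective:valence": 4.2, "valence:fixation": -4.8,
                "valence:anxiety": -4.5}
    elif which == "age":
        beta = {"intercept": 50.0, "age": -3.6,
                "perspective:valence": 4.2, "valence:fixation": -4.8,
                "valence:age": 5.4}
    else:
        raise ValueError("which must be 'anxiety' or 'age'")
    return TruthModel(beta=beta, sigma_subject=6.0, sigma_scene=4.0,
                      sigma_resid=20.0)


@dataclass(frozen=True)
class GroundTruthEvent:
    kind: str  # fixation | saccade | blink
    onset_ms: float
    offset_ms: float
    centroid_px: tuple[float, float] | None = None


@dataclass(frozen=True)
class TrialSpec:
    """Everything one gaze trial needs: identity, timing, layout, artifacts."""

    trial_id: str
    scene_id: int
    aois: tuple[tuple[float, float, float, float], ...]  # scene px
    cross_duration_ms: float
    rating_latency_ms: float
    drift_px: tuple[float, float] = (0.0, 0.0)
    y_bias_px: float = 0.0
    #: optional scripted scene-window fixations as (duration_ms, x_px, y_px)
    #: in *screen* pixels; None -> random scanpath.
    scripted_fixations: tuple[tuple[float, float, float], ...] | None = None
    #: participant's baseline pupil diameter; None -> drawn from the config
    #: range per trial.
    pupil_base_mm: float | None = None
    perspective: str | None = None
    valence: str | None = None


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(n_participants: int, seed: int) -> pd.DataFrame:
    """Counterbalanced trial design.

    Each participant sees all 72 scenes exactly once, in a random order cut
    into 6 blocks of 12; each scene is assigned to the self condition for
    half the participants (+-1 when the count is odd), and statement valence
    is likewise counterbalanced within perspective sets.
    """
    if n_participants < 2:
        raise ValueError("counterbalancing needs at least 2 participants")
    rng = np.random.default_rng(seed)
    scenes = np.arange(1, N_SCENES + 1)
    half = rng.permutation(scenes)
    set_a, set_b = set(half[:N_SCENES // 2]), set(half[N_SCENES // 2:])
    # independent split for valence counterbalancing
    vhalf = rng.permutation(scenes)
    vset_a = set(vhalf[:N_SCENES // 2])

    rows = []
    for p in range(n_participants):
        pid = f"p{p + 1:02d}"
        self_scenes = set_a if p % 2 == 0 else set_b
        pos_scenes = vset_a if (p // 2) % 2 == 0 else set(scenes) - vset_a
        order = rng.permutation(scenes)
        for i, scene in enumerate(order):
            rows.append({
                "participant_id": pid,
                "trial_id": f"{pid}_t{i + 1:02d}",
                "trial": i + 1,
                "block": i // TRIALS_PER_BLOCK + 1,
                "trial_index_in_block": i % TRIALS_PER_BLOCK + 1,
                "scene_id": int(scene),
                "perspective": "self" if scene in self_scenes else "other",
                "valence": "positive" if scene in pos_scenes else "negative",
                "protagonist_side": "left" if rng.random() < 0.5 else "right",
            })
    return pd.DataFrame(rows)


def generate_aois(seed: int, n_scenes: int = N_SCENES,
                  scene_px: tuple[int, int] = (1200, 750),
                  ) -> dict[int, list[tuple[float, float, float, float]]]:
    """Per-scene peer-face rectangles (scene pixels), 1-3 faces per scene in
    the upper two thirds of the image."""
    rng = np.random.default_rng(seed)
    w, h = scene_px
    aois: dict[int, list[tuple[float, float, float, float]]] = {}
    for scene in range(1, n_scenes + 1):
        n_faces = int(rng.integers(1, 4))
        rects = []
        for _ in range(n_faces):
            rw = float(rng.uniform(90, 150))
            rh = float(rng.uniform(100, 160))
            rx = float(rng.uniform(0, w - rw))
            ry = float(rng.uniform(0, 2 * h / 3 - rh))
            rects.append((rx, ry, rw, rh))
        aois[scene] = rects
    return aois


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

def simulate_participants(n: int, seed: int) -> pd.DataFrame:
    """Questionnaire item responses and ages.

    SAS-A totals are drawn around the community norms for adolescent females
    (mean ~47, sd ~10.6) and spread over the 18 scored items; PDS responses
    sit in the mid-to-late pubertal range; ages are uniform on [14, 19.75].
    """
    if n < 1:
        raise ValueError("need n >= 1 participants")
    rng = np.random.default_rng(seed)
    from .questionnaires import SAS_A_FILLER_ITEMS, SAS_A_N_ITEMS

    rows = []
    for p in range(n):
        pid = f"p{p + 1:02d}"
        target = float(np.clip(rng.normal(46.9, 10.6), 18, 90))
        item_mean = target / 18.0
        row: dict = {"participant_id": pid,
                     "age": float(rng.uniform(14.0, 19.75))}
        for i in range(1, SAS_A_N_ITEMS + 1):
            if i in SAS_A_FILLER_ITEMS:
                row[f"sas_{i:02d}"] = int(rng.integers(1, 6))
            else:
                row[f"sas_{i:02d}"] = int(np.clip(
                    round(rng.normal(item_mean, 0.9)), 1, 5))
        for i in range(1, 5):
            row[f"pds_{i}"] = int(rng.choice([2, 3, 4], p=[0.15, 0.45, 0.40]))
        row["menarche"] = bool(rng.random() < 0.9)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

def _ar1_noise(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter
    innov = np.empty(n)
    innov[0] = rng.normal(0.0, sd)
    innov[1:] = rng.normal(0.0, sd * math.sqrt(1 - rho * rho), size=n - 1)
    return lfilter([1.0], [1.0, -rho], innov)


def _scanpath(spec: TrialSpec, config: SimulationConfig,
              rng: np.random.Generator, dt: float,
              ) -> tuple[np.ndarray, np.ndarray, list[GroundTruthEvent], float]:
    """Noise-free eye path on the sample grid plus ground-truth events.

    Returns (x, y, events, total_duration_ms); times are trial-relative with
    fixation-cross onset at 0.
    """
    geom = config.geometry
    k_px = deg_to_px(1.0, geom)
    cross = scene_center_px(geom)
    sx, sy, sw, sh = scene_rect_px(geom)
    scene_on = spec.cross_duration_ms
    scene_off = scene_on + config.scene_duration_ms
    end_ms = scene_off + config.statement_duration_ms + spec.rating_latency_ms
    n = int(round(end_ms / dt))
    t = np.arange(n) * dt

    # plan (duration_ms, target) segments: cross fixation, then scene fixations
    plan: list[tuple[str, float, tuple[float, float]]] = []
    plan.append(("fixation", scene_on, cross))
    prev = cross
    if spec.scripted_fixations is not None:
        script = list(spec.scripted_fixations)
        for dur, fx, fy in script:
            amp_deg = math.hypot(fx - prev[0], fy - prev[1]) / k_px
            if amp_deg > 1e-9:
                sac = float(np.clip(amp_deg * config.saccade_ms_per_deg,
                                    *config.saccade_duration_ms))
                plan.append(("saccade", sac, (fx, fy)))
            plan.append(("fixation", float(dur), (fx, fy)))
            prev = (fx, fy)
    else:
        budget = end_ms - scene_on
        used = 0.0
        while used < budget:
            for _ in range(30):
                if rng.random() < config.p_fixation_on_aoi and spec.aois:
                    r = spec.aois[int(rng.integers(len(spec.aois)))]
                    tx = sx + r[0] + rng.uniform(0.25, 0.75) * r[2]
                    ty = sy + r[1] + rng.uniform(0.25, 0.75) * r[3]
                else:
                    tx = sx + rng.uniform(0.05, 0.95) * sw
                    ty = sy + rng.uniform(0.05, 0.95) * sh
                if (math.hypot(tx - prev[0], ty - prev[1]) / k_px
                        >= config.min_target_separation_deg):
                    break
            amp_deg = math.hypot(tx - prev[0], ty - prev[1]) / k_px
            sac = float(np.clip(amp_deg * config.saccade_ms_per_deg,
                                *config.saccade_duration_ms))
            dur = float(rng.uniform(*config.fixation_duration_ms))
            plan.append(("saccade", sac, (tx, ty)))
            plan.append(("fixation", dur, (tx, ty)))
            prev = (tx, ty)
            used += sac + dur

    # lay the plan onto the sample grid
    x = np.empty(n)
    y = np.empty(n)
    events: list[GroundTruthEvent] = []
    i = 0
    pos = cross
    for kind, dur_ms, target in plan:
        n_seg = max(1, int(round(dur_ms / dt)))
        j = min(i + n_seg, n)
        if j <= i:
            break
        if kind == "fixation":
            x[i:j] = target[0]
            y[i:j] = target[1]
            events.append(GroundTruthEvent("fixation", float(t[i]),
                                           float(t[j - 1]), target))
        else:
            frac = np.linspace(0.0, 1.0, j - i, endpoint=False) + 1.0 / (j - i)
            x[i:j] = pos[0] + frac * (target[0] - pos[0])
            y[i:j] = pos[1] + frac * (target[1] - pos[1])
            events.append(GroundTruthEvent("saccade", float(t[i]), float(t[j - 1])))
        pos = target
        i = j
        if i >= n:
            break
    if i < n:  # hold the last target through any remaining samples
        x[i:] = pos[0]
        y[i:] = pos[1]
        if events and events[-1].kind == "fixation":
            last = events.pop()
            events.append(GroundTruthEvent("fixation", last.onset_ms,
                                           float(t[-1]), last.centroid_px))
    return x, y, events, end_ms


def simulate_gaze_trial(spec: TrialSpec, config: SimulationConfig,
                        seed: int | np.random.Generator,
                        ) -> tuple[GazeStream, list[GroundTruthEvent]]:
    """One trial of 300 Hz binocular gaze with ground-truth events.

    Times are trial-relative (fixation-cross onset at 0 ms).  Blinks collapse
    both pupil channels with a per-sample diameter change above the blink
    threshold and invalidate the tracker flag; fixation samples scatter
    around the event centroid with AR(1) noise; the trial's constant drift
    offset and any participant vertical bias are added to the gaze channels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geom = config.geometry
    dt = 1000.0 / config.sampling_rate_hz
    x, y, events, end_ms = _scanpath(spec, config, rng, dt)
    n = len(x)
    t = np.arange(n) * dt
    k_px = deg_to_px(1.0, geom)

    def noisy(base: np.ndarray) -> np.ndarray:
        return base + k_px * _ar1_noise(n, config.noise_sd_deg,
                                        config.noise_ar1_rho, rng)

    lx, ly = noisy(x), noisy(y)
    rx, ry = noisy(x), noisy(y)
    dx, dy = spec.drift_px
    lx = lx + dx; rx = rx + dx
    ly = ly + dy + spec.y_bias_px; ry = ry + dy + spec.y_bias_px

    base = (spec.pupil_base_mm if spec.pupil_base_mm is not None
            else rng.uniform(*config.pupil_base_mm))
    lp = base + _ar1_noise(n, 0.02, 0.995, rng)
    rp = base + 0.05 + _ar1_noise(n, 0.02, 0.995, rng)
    tracker = np.ones(n, dtype=bool)

    # blinks inside the scene window
    scene_on = spec.cross_duration_ms
    scene_off = scene_on + config.scene_duration_ms
    if rng.random() < config.blink_probability:
        dur_ms = rng.uniform(*config.blink_duration_ms)
        n_blink = max(6, int(round(dur_ms / dt)))
        start_ms = rng.uniform(scene_on + 200.0,
                               max(scene_on + 201.0, scene_off - dur_ms - 200.0))
        b0 = int(round(start_ms / dt))
        b1 = min(b0 + n_blink, n)
        ramp = max(3, min(10, (b1 - b0) // 3))
        profile = np.ones(b1 - b0)
        profile[:ramp] = np.linspace(1.0, 0.0, ramp, endpoint=False)
        profile[-ramp:] = np.linspace(0.0, 1.0, ramp, endpoint=False)[::-1]
        profile[ramp:-ramp] = 0.0
        floor = 0.3
        lp[b0:b1] = floor + profile * (lp[b0:b1] - floor)
        rp[b0:b1] = floor + profile * (rp[b0:b1] - floor)
        tracker[b0:b1] = False
        blink = GroundTruthEvent("blink", float(t[b0]), float(t[b1 - 1]))
        events = _carve(events, blink, dt)
        events.append(blink)

    if config.validity_noise_rate > 0:
        tracker &= rng.random(n) >= config.validity_noise_rate

    stream = GazeStream(t, lx, ly, rx, ry, lp, rp, tracker)
    events.sort(key=lambda e: e.onset_ms)
    return stream, events


#: fixation fragments shorter than this (the detector's own minimum) are
#: dropped from the ground truth when a blink carves up an event.
_MIN_TRUTH_FIXATION_MS = 75.0


def _carve(events: list[GroundTruthEvent], blink: GroundTruthEvent,
           dt: float) -> list[GroundTruthEvent]:
    """Split/trim fixation and saccade events around a blink interval so the
    ground-truth event list stays non-overlapping."""
    out: list[GroundTruthEvent] = []
    for ev in events:
        if ev.offset_ms < blink.onset_ms or ev.onset_ms > blink.offset_ms:
            out.append(ev)
            continue
        left = (ev.onset_ms, blink.onset_ms - dt)
        right = (blink.offset_ms + dt, ev.offset_ms)
        for a, b in (left, right):
            if b <= a:
                continue
            if ev.kind == "fixation" and (b - a) < _MIN_TRUTH_FIXATION_MS:
                continue
            out.append(GroundTruthEvent(ev.kind, a, b, ev.centroid_px))
    return out


def _wander(duration_ms: float, config: SimulationConfig,
            rng: np.random.Generator, dt: float,
            pupil_base_mm: float | None = None) -> GazeStream:
    """Inter-trial gaze: a few fixations at random screen points."""
    geom = config.geometry
    n = int(round(duration_ms / dt))
    t = np.arange(n) * dt
    w, h = geom.screen_px
    x = np.empty(n)
    y = np.empty(n)
    i = 0
    while i < n:
        j = min(n, i + int(round(rng.uniform(300, 900) / dt)))
        x[i:j] = rng.uniform(0.1 * w, 0.9 * w)
        y[i:j] = rng.uniform(0.1 * h, 0.9 * h)
        i = j
    k_px = deg_to_px(1.0, geom)
    lx = x + k_px * _ar1_noise(n, config.noise_sd_deg, config.noise_ar1_rho, rng)
    ly = y + k_px * _ar1_noise(n, config.noise_sd_deg, config.noise_ar1_rho, rng)
    rx = x + k_px * _ar1_noise(n, config.noise_sd_deg, config.noise_ar1_rho, rng)
    ry = y + k_px * _ar1_noise(n, config.noise_sd_deg, config.noise_ar1_rho, rng)
    base = (pupil_base_mm if pupil_base_mm is not None
            else rng.uniform(*config.pupil_base_mm))
    lp = base + _ar1_noise(n, 0.02, 0.995, rng)
    rp = base + 0.05 + _ar1_noise(n, 0.02, 0.995, rng)
    return GazeStream(t, lx, ly, rx, ry, lp, rp, np.ones(n, dtype=bool))


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

def simulate_ratings(design: pd.DataFrame, fixation_time_ms: np.ndarray,
                     truth: TruthModel, seed: int) -> pd.DataFrame:
    """Interpretation ratings from the generative mixed model.

    ``design`` needs perspective, valence, participant_id, scene_id and the
    covariate column named in the truth betas (anxiety or age).  Predictors
    are coded exactly as in the fitted models (factors -0.5/+0.5, continuous
    predictors z-scored), so the truth coefficients live on the fitted scale.
    Ratings are truncated to [0, 100].
    """
    rng = np.random.default_rng(seed)
    covariates = [c for c in ("anxiety", "age") if c in {
        f for term in truth.beta for f in term.split(":")}]
    which = covariates[0] if covariates else "anxiety"
    records = _inf.code_predictors(design, fixation_time_ms, which)
    factors = _inf.model_factors(which)
    terms = _inf.global_terms(factors)
    names = ["intercept"] + [_inf.term_name(t) for t in terms]
    canon = {}
    for key, val in truth.beta.items():
        name = key if key == "intercept" else _inf.term_name(
            tuple(sorted(key.split(":"), key=factors.index)))
        if name not in names:
            raise ValueError(f"unknown truth term {key!r}")
        canon[name] = val
    beta = np.array([canon.get(nm, 0.0) for nm in names])
    X = _inf.design_matrix(records, terms, factors)

    subj_codes, subj_idx = np.unique(records["subject_id"], return_inverse=True)
    scene_codes, scene_idx = np.unique(records["scene_id"], return_inverse=True)
    b_s = rng.normal(0.0, truth.sigma_subject, size=len(subj_codes))
    b_c = rng.normal(0.0, truth.sigma_scene, size=len(scene_codes))
    eps = rng.normal(0.0, truth.sigma_resid, size=len(records))
    rating = X @ beta + b_s[subj_idx] + b_c[scene_idx] + eps
    out = design[["trial_id"]].copy()
    out["rating"] = np.clip(rating, 0.0, 100.0)
    return out


def simulate_model_records(n_participants: int, truth: TruthModel | None = None,
                           which: str = "anxiety", seed: int = 0) -> pd.DataFrame:
    """One modelling-level replicate for the parameter-recovery harness.

    Generates a counterbalanced design, questionnaire-derived covariates and
    log-normal AOI dwell times (median ~1.1 s of a 5 s window), draws ratings
    from the truth model, and returns the coded record table ready for
    :func:`peergaze.inference.run_analysis`.  Bypasses the gaze signal chain:
    recovery of the *statistical* machinery is what this harness isolates.
    """
    if truth is None:
        truth = default_truth(which)
    ss = np.random.SeedSequence(seed)
    s1, s2, s3, s4 = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))
    design = generate_design(n_participants, s1)
    parts = simulate_participants(n_participants, s2)
    from .questionnaires import score_sas_a
    sas_cols = [c for c in parts.columns if c.startswith("sas_")]
    parts["anxiety"] = [score_sas_a(list(r)).total
                        for r in parts[sas_cols].to_numpy()]
    d = design.merge(parts[["participant_id", "anxiety", "age"]],
                     on="participant_id")
    rng = np.random.default_rng(s3)
    fixation_ms = np.minimum(rng.lognormal(7.0, 0.5, size=len(d)), 5000.0)
    ratings = simulate_ratings(d, fixation_ms, truth, s4)
    records = _inf.code_predictors(d, fixation_ms, which)
    records.insert(0, "rating", ratings["rating"].to_numpy())
    records["trial_id"] = d["trial_id"].to_numpy()
    return records


def true_aoi_fixation_time(events: list[GroundTruthEvent],
                           aois: list[tuple[float, float, float, float]],
                           scene_window_ms: tuple[float, float],
                           geometry: ScreenGeometry) -> float:
    """Ground-truth AOI dwell time (ms) from simulated fixation events."""
    ox, oy = scene_rect_px(geometry)[:2]
    w0, w1 = scene_window_ms
    total = 0.0
    for ev in events:
        if ev.kind != "fixation" or ev.centroid_px is None:
            continue
        a, b = max(ev.onset_ms, w0), min(ev.offset_ms, w1)
        if b <= a:
            continue
        cx, cy = ev.centroid_px
        for rx, ry, rw, rh in aois:
            if ox + rx <= cx < ox + rx + rw and oy + ry <= cy < oy + ry + rh:
                total += b - a
                break
    return min(total, w1 - w0)


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    design: pd.DataFrame
    participants: pd.DataFrame
    aois: dict[int, list[tuple[float, float, float, float]]]
    streams: dict[str, GazeStream]
    events: pd.DataFrame            # participant_id, trial_id, event, t_ms
    ratings: pd.DataFrame           # trial_id, rating
    truth_events: dict[str, list[GroundTruthEvent]]  # per trial_id
    truth_model: TruthModel
    true_fixation_time_ms: pd.DataFrame  # trial_id, true_aoi_fixation_ms


def simulate_dataset(config: SimulationConfig,
                     truth: TruthModel | None = None,
                     which: str = "anxiety") -> SimulatedDataset:
    """Generate a complete synthetic study: design, questionnaires, per-
    participant continuous gaze streams with event logs, and ratings drawn
    from the ground-truth model using *true* AOI dwell times."""
    ss = np.random.SeedSequence(config.seed)
    s_design, s_aoi, s_part, s_rate, s_gaze = ss.spawn(5)
    if truth is None:
        truth = default_truth(which)
    design = generate_design(config.n_participants, int(s_design.generate_state(1)[0] % 2**31))
    aois = generate_aois(int(s_aoi.generate_state(1)[0] % 2**31))
    participants = simulate_participants(config.n_participants,
                                         int(s_part.generate_state(1)[0] % 2**31))
    from .questionnaires import score_sas_a
    sas_cols = [c for c in participants.columns if c.startswith("sas_")]
    participants = participants.copy()
    participants["anxiety"] = [
        score_sas_a(list(r)).total for r in participants[sas_cols].to_numpy()]

    dt = 1000.0 / config.sampling_rate_hz
    geom = config.geometry
    streams: dict[str, GazeStream] = {}
    truth_events: dict[str, list[GroundTruthEvent]] = {}
    event_rows = []
    true_fix_rows = []
    gaze_rngs = {pid: np.random.default_rng(child)
                 for pid, child in zip(participants["participant_id"],
                                       s_gaze.spawn(config.n_participants))}

    for pid, ptrials in design.groupby("participant_id", sort=True):
        rng = gaze_rngs[pid]
        chunks: list[GazeStream] = []
        t_offset = 0.0
        pupil_base = float(rng.uniform(*config.pupil_base_mm))
        for row in ptrials.sort_values("trial").itertuples(index=False):
            spec = TrialSpec(
                trial_id=row.trial_id,
                scene_id=int(row.scene_id),
                aois=tuple(tuple(r) for r in aois[int(row.scene_id)]),
                cross_duration_ms=float(rng.uniform(*config.cross_duration_ms)),
                rating_latency_ms=float(rng.uniform(*config.rating_latency_ms)),
                drift_px=(float(rng.normal(0, config.drift_offset_sd_px)),
                          float(rng.normal(0, config.drift_offset_sd_px))),
                y_bias_px=config.y_bias_px,
                perspective=row.perspective,
                valence=row.valence,
                pupil_base_mm=pupil_base,
            )
            st, evs = simulate_gaze_trial(spec, config, rng)
            scene_on = spec.cross_duration_ms
            scene_off = scene_on + config.scene_duration_ms
            stmt_off = scene_off + config.statement_duration_ms
            rating_t = stmt_off + spec.rating_latency_ms
            marks = {"fixation_onset": 0.0, "scene_onset": scene_on,
                     "scene_offset": scene_off, "statement_offset": stmt_off,
                     "rating": min(rating_t, float(st.t_ms[-1]))}
            for name, tm in marks.items():
                event_rows.append({"participant_id": pid, "trial_id": row.trial_id,
                                   "event": name, "t_ms": tm + t_offset})
            truth_events[row.trial_id] = [
                replace(e, onset_ms=e.onset_ms + t_offset,
                        offset_ms=e.offset_ms + t_offset) for e in evs]
            true_fix_rows.append({
                "trial_id": row.trial_id,
                "true_aoi_fixation_ms": true_aoi_fixation_time(
                    evs, list(aois[int(row.scene_id)]), (scene_on, scene_off),
                    geom)})
            shifted = st.copy()
            shifted.t_ms = st.t_ms + t_offset
            chunks.append(shifted)
            t_offset += len(st) * dt
            iti = _wander(rng.uniform(*config.iti_ms), config, rng, dt,
                          pupil_base_mm=pupil_base)
            iti.t_ms = iti.t_ms + t_offset
            chunks.append(iti)
            t_offset += len(iti) * dt
        streams[pid] = GazeStream(
            *(np.concatenate([getattr(c, f) for c in chunks])
              for f in ("t_ms", "lx", "ly", "rx", "ry",
                        "lpupil", "rpupil", "tracker_valid")))

    events = pd.DataFrame(event_rows)
    true_fix = pd.DataFrame(true_fix_rows)
    design_cov = design.merge(
        participants[["participant_id", "anxiety", "age"]], on="participant_id")
    design_cov = design_cov.merge(true_fix, on="trial_id")
    design_cov = design_cov.set_index(design.index)
    ratings = simulate_ratings(
        design_cov, design_cov["true_aoi_fixation_ms"].to_numpy(), truth,
        int(s_rate.generate_state(1)[0] % 2**31))
    return SimulatedDataset(config, design, participants, aois, streams,
                            events, ratings, truth_events, truth, true_fix)
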