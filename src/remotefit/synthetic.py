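"""Synthetic fixtures with known ground truth.

Three generators emulate the raw material of the toolkit so every pipeline
is testable without any recorded data:

* a GPS track of a back-and-forth walk on a straight course, with
  time-correlated position noise and optional glitch fixes;
* a pose-keypoint stream of sit-to-stand cycles on a 2-D stick figure,
  with correct or incorrect arm posture;
* a subject x session score table from a variance-components model (plus a
  paired device-vs-gold table), the generating model behind the ICC.

All generators are deterministic given their spec (which includes the
seed) and return the truth alongside the data.

GPS noise model: smartphone position error is dominated by slowly drifting
biases (atmospheric delay, ephemeris, receiver filtering), not white
noise, so the error is first-order Gauss-Markov (an Ornstein-Uhlenbeck
process) per axis with marginal SD ``noise_sd`` and correlation time
``noise_tau_s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .geo_walk import EARTH_RADIUS_M, GpsFix, GpsTrack
from .sts import COCO_JOINTS, Keypoint, PoseFrame, PoseSequence

SpeedProfile = Union[float, Callable[[np.ndarray], np.ndarray]]


# ---------------------------------------------------------------------------
# GPS walk


@dataclass
class WalkSimSpec:
    """Back-and-forth walk on a straight course (study protocol: round
    trips on a 100 m line for 360 s, one fix every 5 s)."""

    course_length: float = 100.0
    speed: SpeedProfile = 1.5
    duration: float = 360.0
    fix_interval: float = 5.0
    noise_sd: float = 0.0
    noise_tau_s: float = 180.0
    outlier_rate: float = 0.0
    outlier_speed: float = 15.0
    accuracy_m: float = 8.0
    origin: tuple[float, float] = (45.19, 5.73)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.course_length <= 0 or self.duration <= 0 or self.fix_interval <= 0:
            raise InvalidInputError("course, duration and fix interval must be positive")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise InvalidInputError("outlier_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")


def _fold(s: np.ndarray, length: float) -> np.ndarray:
    """Triangle-wave fold of cumulative path length onto a [0, length] course."""
    p = np.mod(s, 2.0 * length)
    return np.where(p <= length, p, 2.0 * length - p)


def _ou_noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd`` and lag-1 corr ``rho``."""
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - rho * rho), size=n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + innov[i - 1]
    return e


def simulate_gps_walk(spec: WalkSimSpec) -> tuple[GpsTrack, dict]:
    """Simulate a walk track; returns (track, {"distance_m": true distance}).

    The true path is back-and-forth along a local-east geodesic segment of
    ``course_length`` at the speed profile; fixes are the true positions
    plus Gauss-Markov noise; with probability ``outlier_rate`` a fix is
    displaced perpendicular to the course so the incoming interval implies
    ``outlier_speed``.  Path construction uses a flat local tangent plane
    around ``origin`` (adequate below 1 km) converted to WGS84 lat/lon.
    """
    rng = np.random.default_rng(spec.seed)
    ts = np.arange(0.0, spec.duration + spec.fix_interval / 2.0, spec.fix_interval)
    if callable(spec.speed):
        v = np.asarray(spec.speed(ts), dtype=float)
        # cumulative trapezoid for path length
        s = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0 * np.diff(ts))])
        truth = float(s[-1])
        v_nominal = v
    else:
        s = float(spec.speed) * ts
        truth = float(spec.speed) * spec.duration
        v_nominal = np.full_like(ts, float(spec.speed))
    x = _fold(s, spec.course_length)
    y = np.zeros_like(x)

    rho = math.exp(-spec.fix_interval / spec.noise_tau_s) if spec.noise_tau_s > 0 else 0.0
    x = x + _ou_noise(rng, ts.size, spec.noise_sd, rho)
    y = y + _ou_noise(rng, ts.size, spec.noise_sd, rho)

    if spec.outlier_rate > 0:
        hits = rng.random(ts.size) < spec.outlier_rate
        hits[0] = False
        for i in np.flatnonzero(hits):
            vn = v_nominal[i]
            dt = ts[i] - ts[i - 1]
            delta = dt * math.sqrt(max(0.0, spec.outlier_speed ** 2 - vn ** 2))
            y[i] += delta * (1.0 if rng.random() < 0.5 else -1.0)

    lat0, lon0 = spec.origin
    lat = lat0 + np.degrees(y / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
    fixes = [
        GpsFix(float(t), float(la), float(lo), spec.accuracy_m)
        for t, la, lo in zip(ts, lat, lon)
    ]
    return GpsTrack(fixes), {"distance_m": truth}


# ---------------------------------------------------------------------------
# sit-to-stand stick figure


@dataclass
class FigureGeometry:
    """Stick-figure segment lengths in pixels (side-ish view, fixed so the
    angle-to-keypoint mapping is invertible)."""

    thigh: float = 90.0
    shank: float = 90.0
    trunk: float = 130.0
    shoulder_breadth: float = 80.0
    hip_breadth: float = 24.0
    head_offset: float = 35.0
    image_size: tuple[int, int] = (640, 480)


@dataclass
class StsSimSpec:
    """Sit-to-stand cycles: sinusoidal knee/hip angles between sitting
    (~90 deg) and standing (~175 deg)."""

    n_cycles: int = 12
    cycle_duration: float = 2.5
    fraction_bad_arms: float = 0.0
    angle_noise_sd: float = 0.0
    fps: float = 30.0
    sit_angle: float = 90.0
    stand_angle: float = 175.0
    tail_s: float = 2.0
    geometry: FigureGeometry = field(default_factory=FigureGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.cycle_duration <= 0 or self.fps <= 0:
            raise InvalidInputError("n_cycles, cycle_duration and fps must be positive")
        if not 0.0 <= self.fraction_bad_arms <= 1.0:
            raise InvalidInputError("fraction_bad_arms must be in [0, 1]")


def _rot(v: tuple[float, float], deg: float) -> tuple[float, float]:
    a = math.radians(deg)
    return (v[0] * math.cos(a) - v[1] * math.sin(a), v[0] * math.sin(a) + v[1] * math.cos(a))


def stick_figure_frame(
    t: float,
    knee_deg: float,
    hip_deg: float,
    arms_crossed: bool = True,
    geometry: Optional[FigureGeometry] = None,
    confidence: float = 0.95,
) -> PoseFrame:
    """Build a 17-keypoint frame realizing the given knee and hip angles.

    The figure is constructed in a y-up plane anchored at the ankles
    (shank vertical), then flipped into image coordinates (y down).  With
    arms crossed the wrists sit at the chest (shoulder midpoint); otherwise
    they hang well outside the chest radius.
    """
    g = geometry or FigureGeometry()
    kr, hr = math.radians(knee_deg), math.radians(hip_deg)
    ankle = (0.0, 0.0)
    knee = (0.0, g.shank)
    # knee->ankle points down; rotate it ccw by the knee angle to get knee->hip
    thigh_dir = (math.sin(kr), -math.cos(kr))
    hip = (knee[0] + g.thigh * thigh_dir[0], knee[1] + g.thigh * thigh_dir[1])
    hip_to_knee = (-thigh_dir[0], -thigh_dir[1])
    trunk_dir = _rot(hip_to_knee, -hip_deg)
    top = (hip[0] + g.trunk * trunk_dir[0], hip[1] + g.trunk * trunk_dir[1])

    half_sb = g.shoulder_breadth / 2.0
    half_hb = g.hip_breadth / 2.0
    mid = top
    if arms_crossed:
        wrists = {
            "left_wrist": (mid[0] + 0.1 * g.shoulder_breadth, mid[1] - 0.15 * g.trunk),
            "right_wrist": (mid[0] - 0.1 * g.shoulder_breadth, mid[1] - 0.15 * g.trunk),
        }
    else:  # arms hanging by the sides, far from the chest
        wrists = {
            "left_wrist": (mid[0] + 0.3 * g.shoulder_breadth, mid[1] - 0.9 * g.trunk),
            "right_wrist": (mid[0] - 0.3 * g.shoulder_breadth, mid[1] - 0.9 * g.trunk),
        }
    pts = {
        "left_ankle": (ankle[0] + half_hb, ankle[1]),
        "right_ankle": (ankle[0] - half_hb, ankle[1]),
        "left_knee": (knee[0] + half_hb, knee[1]),
        "right_knee": (knee[0] - half_hb, knee[1]),
        "left_hip": (hip[0] + half_hb, hip[1]),
        "right_hip": (hip[0] - half_hb, hip[1]),
        "left_shoulder": (top[0] + half_sb, top[1]),
        "right_shoulder": (top[0] - half_sb, top[1]),
        "nose": (top[0], top[1] + g.head_offset),
        "left_eye": (top[0] + 6.0, top[1] + g.head_offset + 5.0),
        "right_eye": (top[0] - 6.0, top[1] + g.head_offset + 5.0),
        "left_ear": (top[0] + 12.0, top[1] + g.head_offset + 2.0),
        "right_ear": (top[0] - 12.0, top[1] + g.head_offset + 2.0),
        **wrists,
    }
    pts["left_elbow"] = (
        (pts["left_shoulder"][0] + pts["left_wrist"][0]) / 2.0,
        (pts["left_shoulder"][1] + pts["left_wrist"][1]) / 2.0,
    )
    pts["right_elbow"] = (
        (pts["right_shoulder"][0] + pts["right_wrist"][0]) / 2.0,
        (pts["right_shoulder"][1] + pts["right_wrist"][1]) / 2.0,
    )
    w, h = g.image_size
    ox, oy = w * 0.45, h * 0.92  # figure anchored near the bottom of the frame
    keypoints = {
        name: Keypoint(ox + p[0], oy - p[1], confidence) for name, p in pts.items()
    }
    assert set(keypoints) == set(COCO_JOINTS)
    return PoseFrame(t, keypoints)


def simulate_sts_sequence(spec: StsSimSpec) -> tuple[PoseSequence, dict]:
    """Simulate a sit-to-stand keypoint stream.

    Returns (sequence, truth) with truth = {"correct": c, "incorrect": i},
    counting cycles whose onset lies inside the 30-s scoring window;
    ``round(fraction_bad_arms * n_cycles)`` cycles are performed with the
    arms hanging instead of crossed.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.cycle_duration
    n_bad = int(round(spec.fraction_bad_arms * spec.n_cycles))
    bad = set(rng.choice(spec.n_cycles, size=n_bad, replace=False)) if n_bad else set()
    total = spec.n_cycles * T + spec.tail_s
    ts = np.arange(0.0, total, 1.0 / spec.fps)
    amp = (spec.stand_angle - spec.sit_angle) / 2.0
    frames = []
    for t in ts:
        cycle = int(t // T)
        if cycle < spec.n_cycles:
            phase = (t % T) / T
            angle = spec.sit_angle + amp * (1.0 - math.cos(2.0 * math.pi * phase))
            crossed = cycle not in bad
        else:
            angle = spec.sit_angle
            crossed = True
        knee = angle + rng.normal(0.0, spec.angle_noise_sd) if spec.angle_noise_sd else angle
        hip = angle + rng.normal(0.0, spec.angle_noise_sd) if spec.angle_noise_sd else angle
        frames.append(
            stick_figure_frame(float(t), knee, hip, arms_crossed=crossed, geometry=spec.geometry)
        )
    onsets = [i * T for i in range(spec.n_cycles)]
    in_win = [i for i, on in enumerate(onsets) if on < 30.0]
    incorrect = sum(1 for i in in_win if i in bad)
    truth = {"correct": len(in_win) - incorrect, "incorrect": incorrect}
    return PoseSequence(frames, fps=spec.fps), truth


# ---------------------------------------------------------------------------
# validation study


_BRANDS = ("iPhone", "Samsung Galaxy", "Google Pixel", "Huawei", "Xiaomi", "OnePlus", "Realme")
_BRAND_P = (0.44, 0.26, 0.14, 0.06, 0.06, 0.02, 0.02)


@dataclass
class StudySimSpec:
    """Variance-components score model behind the validation study.

    score_ijs = mu + b_i + e_ij, b ~ N(0, sigma_between^2),
    e ~ N(0, sigma_error^2); the paired device score is
    gold + device_bias + N(0, device_error_sd^2).  Defaults mirror the
    validation study's 6MWT summary statistics (53 subjects, 3 sessions,
    mean 704.55 m, total SD 79.13 m at ICC 0.78; validity mean difference
    8.96 m with LoA half-width 85.92 m).
    """

    n_subjects: int = 53
    n_sessions: int = 3
    mu: float = 704.55
    sigma_between: float = 69.9
    sigma_error: float = 37.1
    device_bias: float = 8.96
    device_error_sd: float = 43.8
    age_effect: float = 0.0       # score units per year (age centered at 33)
    bmi_effect: float = 0.0       # score units per kg/m^2 (centered at 22.6)
    brand_effect_sd: float = 0.0  # SD of per-brand offsets
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_between < 0 or self.sigma_error < 0 or self.device_error_sd < 0:
            raise InvalidInputError("standard deviations must be >= 0")
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise InvalidInputError("need at least one subject and one session")


def simulate_validation_study(
    spec: StudySimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a validation study.

    Returns (repeated_measures, pairs, truth): a long subject x session
    score table with per-subject covariates, a paired device-vs-gold
    table (one pair per session), and
    truth = {"icc": sb^2/(sb^2+se^2), "sem": se}.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_subjects, spec.n_sessions
    age = np.clip(rng.normal(33.0, 11.0, n), 18.0, 80.0)
    bmi = np.clip(rng.normal(22.6, 2.8, n), 15.0, 40.0)
    brand = rng.choice(_BRANDS, size=n, p=_BRAND_P)
    brand_offsets = dict(
        zip(_BRANDS, rng.normal(0.0, spec.brand_effect_sd, len(_BRANDS)))
        if spec.brand_effect_sd
        else zip(_BRANDS, np.zeros(len(_BRANDS)))
    )
    b = rng.normal(0.0, spec.sigma_between, n)
    e = rng.normal(0.0, spec.sigma_error, (n, k))
    fixed = (
        spec.mu
        + spec.age_effect * (age - 33.0)
        + spec.bmi_effect * (bmi - 22.6)
        + np.array([brand_offsets[br] for br in brand])
    )
    score = fixed[:, None] + b[:, None] + e
    device = score + spec.device_bias + rng.normal(0.0, spec.device_error_sd, (n, k))

    rows = []
    for i in range(n):
        for j in range(k):
            rows.append(
                {
                    "subject": f"S{i:03d}",
                    "session": j + 1,
                    "score": score[i, j],
                    "age": age[i],
                    "bmi": bmi[i],
                    "phone_brand": brand[i],
                }
            )
    rm = pd.DataFrame(rows)
    pairs = pd.DataFrame(
        {
            "subject": np.repeat([f"S{i:03d}" for i in range(n)], k),
            "session": np.tile(np.arange(1, k + 1), n),
            "device": device.ravel(),
            "gold": score.ravel(),
        }
    )
    var_total = spec.sigma_between ** 2 + spec.sigma_error ** 2
    truth = {
        "icc": spec.sigma_between ** 2 / var_total if var_total > 0 else float("nan"),
        "sem": spec.sigma_error,
    }
    return rm, pairs, truth
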