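"""GPS six-minute-walk-test (6MWT) distance engine.

A smartphone records a GPS fix roughly every five seconds during a
six-minute outdoor walk.  This module turns that fix stream into a walked
distance: consecutive fixes are joined by great-circle chords, each chord
gives an interval speed, intervals with implausible speed (GPS glitches,
multipath jumps) are flagged and their distance replaced by a
neighbor-median-speed estimate, and the corrected interval distances are
summed.  A start gate mirrors the device behavior of refusing to start
until horizontal accuracy has stabilized, and sex-specific reference
equations (Enright & Sherrill) convert the result into a
percent-of-predicted value.

Geodesy is the haversine formula on a sphere of radius 6,371,000 m; over a
sub-kilometer walking course the ellipsoidal correction is orders of
magnitude below GPS noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import WalkConfig
from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    InvalidTrackError,
    UnusableTrackError,
)

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class GpsFix:
    """One timestamped GPS fix.

    t is seconds since the start of the test; accuracy is the reported
    horizontal accuracy in meters (None when the source did not provide it).
    """

    t: float
    lat: float
    lon: float
    accuracy: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon) and math.isfinite(self.t)):
            raise InvalidInputError("GPS fix with non-finite time or coordinates")
        if not -90.0 <= self.lat <= 90.0:
            raise InvalidInputError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise InvalidInputError(f"longitude {self.lon} outside [-180, 180]")
        if self.accuracy is not None and not self.accuracy >= 0.0:
            raise InvalidInputError("horizontal accuracy must be >= 0")


@dataclass
class GpsTrack:
    """An ordered GPS fix stream with strictly increasing timestamps."""

    fixes: list[GpsFix]

    def __post_init__(self) -> None:
        ts = [f.t for f in self.fixes]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise InvalidTrackError("track timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)

    def accuracy_stream(self) -> list[tuple[float, Optional[float]]]:
        return [(f.t, f.accuracy) for f in self.fixes]


@dataclass
class IntervalSegment:
    """One between-fix interval: chord distance, speed, and outlier status."""

    t_start: float
    t_end: float
    distance: float
    speed: float
    outlier: bool = False
    corrected_distance: float = 0.0

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class WalkResult:
    """Outcome of a 6MWT analysis, in meters."""

    total_distance: float
    raw_distance: float
    n_intervals: int
    n_outliers: int
    predicted_distance: Optional[float] = None
    percent_predicted: Optional[float] = None
    gate_time_s: Optional[float] = None
    borg_dyspnea: Optional[float] = None   # stored only, never computed on
    borg_fatigue: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "total_distance_m": self.total_distance,
            "raw_distance_m": self.raw_distance,
            "n_intervals": self.n_intervals,
            "n_outliers": self.n_outliers,
            "predicted_m": self.predicted_distance,
            "percent_predicted": self.percent_predicted,
            "gate_time_s": self.gate_time_s,
        }


@dataclass(frozen=True)
class Demographics:
    """Age (years), sex, height (cm), weight (kg); BMI is derived."""

    age: float
    sex: str
    height: float
    weight: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("age", "height", "weight"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise InvalidInputError(f"{name} must be a positive number")

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


def haversine_distance(a: GpsFix, b: GpsFix) -> float:
    """Great-circle distance in meters between two fixes (spherical earth)."""
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    s = (
        math.sin((la2 - la1) / 2.0) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(s)))


def segment_track(track: GpsTrack, interval: float = 5.0) -> list[IntervalSegment]:
    """Join consecutive fixes into chord segments with distance and speed.

    Fixes are taken as delivered: a dropped fix simply yields one longer
    segment whose speed uses the actual duration, so speeds stay physically
    meaningful.  ``interval`` is the nominal fix spacing and is only
    validated, not imposed.
    """
    if interval <= 0:
        raise InvalidInputError("fix interval must be positive")
    if len(track) < 2:
        raise InsufficientDataError("at least 2 fixes are needed to compute a distance")
    segments = []
    for a, b in zip(track.fixes, track.fixes[1:]):
        d = haversine_distance(a, b)
        dt = b.t - a.t
        segments.append(
            IntervalSegment(a.t, b.t, d, d / dt, outlier=False, corrected_distance=d)
        )
    return segments


def gate_start(
    accuracy_stream: Iterable[tuple[float, Optional[float]]],
    threshold_m: float = 15.0,
    hold_s: float = 5.0,
) -> Optional[float]:
    """Earliest time at which accuracy has been strictly below ``threshold_m``
    for a contiguous span of at least ``hold_s`` seconds.

    Any sample at or above the threshold (or with missing accuracy) resets
    the span.  Returns None when the stream never stabilizes.
    """
    run_start: Optional[float] = None
    last_t: Optional[float] = None
    for t, acc in accuracy_stream:
        if last_t is not None and t <= last_t:
            raise InvalidTrackError("accuracy stream timestamps must be increasing")
        last_t = t
        if acc is not None and acc < threshold_m:
            if run_start is None:
                run_start = t
            if t - run_start >= hold_s:
                return t
        else:
            run_start = None
    return None


def _nearest_indices(i: int, eligible: np.ndarray, window: int) -> np.ndarray:
    """Indices of the up-to-``window`` eligible segments nearest to i (not i)."""
    cand = np.flatnonzero(eligible)
    cand = cand[cand != i]
    if cand.size == 0:
        return cand
    order = np.argsort(np.abs(cand - i), kind="stable")
    return cand[order[:window]]


def flag_and_correct_outliers(
    segments: Sequence[IntervalSegment],
    vmax: float = 4.0,
    median_factor: float = 3.0,
    window: int = 5,
) -> list[IntervalSegment]:
    """Flag implausible-speed intervals and replace their distance.

    A segment is an outlier when its speed exceeds ``vmax`` or exceeds
    ``median_factor`` times the median speed of the surrounding ``window``
    non-outlier segments.  Each flagged segment's corrected distance is the
    median speed of its nearest non-flagged neighbors times its duration.
    """
    if not segments:
        raise InsufficientDataError("no segments to screen for outliers")
    speeds = np.array([s.speed for s in segments])
    durations = np.array([s.duration for s in segments])
    hard = speeds > vmax
    flagged = hard.copy()
    not_hard = ~hard
    for i in range(len(segments)):
        nb = _nearest_indices(i, not_hard, window)
        if nb.size and speeds[i] > median_factor * np.median(speeds[nb]):
            flagged[i] = True
    if flagged.all():
        raise UnusableTrackError("every interval has an abnormal speed")
    ok = ~flagged
    out = []
    for i, s in enumerate(segments):
        if flagged[i]:
            nb = _nearest_indices(i, ok, window)
            corrected = float(np.median(speeds[nb]) * durations[i])
        else:
            corrected = s.distance
        out.append(
            IntervalSegment(s.t_start, s.t_end, s.distance, s.speed, bool(flagged[i]), corrected)
        )
    return out


def total_walk_distance(segments: Sequence[IntervalSegment]) -> WalkResult:
    """Sum corrected interval distances into a WalkResult."""
    if not segments:
        raise InsufficientDataError("no segments to sum")
    return WalkResult(
        total_distance=float(sum(s.corrected_distance for s in segments)),
        raw_distance=float(sum(s.distance for s in segments)),
        n_intervals=len(segments),
        n_outliers=sum(1 for s in segments if s.outlier),
    )


def enright_sherrill_predicted(d: Demographics) -> float:
    """Predicted six-minute walk distance (m) from the Enright–Sherrill
    healthy-adult reference equations, floored at zero.

    men:   6MWD = 7.57 * height_cm - 5.02 * age - 1.76 * weight_kg - 309
    women: 6MWD = 2.11 * height_cm - 2.29 * weight_kg - 5.78 * age + 667
    """
    if d.sex == "male":
        pred = 7.57 * d.height - 5.02 * d.age - 1.76 * d.weight - 309.0
    else:
        pred = 2.11 * d.height - 2.29 * d.weight - 5.78 * d.age + 667.0
    return max(0.0, pred)


def analyze_walk(
    track: GpsTrack,
    config: Optional[WalkConfig] = None,
    demographics: Optional[Demographics] = None,
    apply_gate: bool = False,
) -> WalkResult:
    """Full 6MWT pipeline: (optional) start gate, windowing to the test
    duration, segmentation, outlier correction, summation, and
    percent-of-predicted when demographics are supplied.

    The device gates BEFORE recording starts, so a recorded test-window
    track is already post-gate and ``apply_gate`` defaults to False; with
    ``apply_gate=True`` the gate runs on the in-track accuracy stream,
    fixes before the ready time are excluded and the scored window is
    [ready, ready + test_duration].
    """
    cfg = config or WalkConfig()
    if len(track) < 2:
        raise InsufficientDataError("at least 2 fixes are needed")
    gate_time = None
    if apply_gate:
        stream = [(t, a) for t, a in track.accuracy_stream() if a is not None]
        if stream:
            gate_time = gate_start(stream, cfg.gate_accuracy_m, cfg.gate_hold_s)
            if gate_time is None:
                raise UnusableTrackError(
                    f"GPS accuracy never stabilized below {cfg.gate_accuracy_m} m "
                    f"for {cfg.gate_hold_s} s"
                )
    start = gate_time if gate_time is not None else track.fixes[0].t
    end = start + cfg.test_duration_s
    kept = [f for f in track.fixes if start <= f.t <= end + 1e-9]
    if len(kept) < 2:
        raise InsufficientDataError("fewer than 2 fixes inside the test window")
    segments = segment_track(GpsTrack(kept), cfg.fix_interval_s)
    segments = flag_and_correct_outliers(
        segments, cfg.vmax_ms, cfg.median_factor, cfg.outlier_window
    )
    result = total_walk_distance(segments)
    result.gate_time_s = gate_time
    if demographics is not None:
        result.predicted_distance = enright_sherrill_predicted(demographics)
        if result.predicted_distance > 0:
            result.percent_predicted = 100.0 * result.total_distance / result.predicted_distance
    return result
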