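"""Readers and writers for the supported on-disk formats.

GPS tracks travel as GPX 1.1 (trkpt lat/lon/time, horizontal accuracy
derived from any hdop element times a meters-per-HDOP factor) or as a
four-column CSV ``t,lat,lon,acc`` (seconds, decimal degrees, meters).
Keypoint streams travel as long-form CSV ``t,joint,x,y,conf`` or as
per-frame JSON records.  Study tables are plain CSV.  All pairs of
reader/writer are lossless roundtrips within floating-point printing
tolerance.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from lxml import etree

from .exceptions import InvalidInputError, ParseError, VocabularyError
from .geo_walk import GpsFix, GpsTrack
from .sts import COCO_JOINTS, Keypoint, PoseFrame, PoseSequence

logger = logging.getLogger("remotefit")

PathLike = Union[str, Path]

_GPX_NS = "http://www.topografix.com/GPX/1/1"
_GPX_EPOCH = _dt.datetime(2023, 1, 1, tzinfo=_dt.timezone.utc)


# ---------------------------------------------------------------------------
# GPS


def read_gps_csv(path: PathLike) -> GpsTrack:
    """Read a ``t,lat,lon,acc`` CSV into a GpsTrack (acc may be blank)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = {"t", "lat", "lon"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if "acc" not in df.columns:
        df["acc"] = float("nan")
    fixes = [
        GpsFix(
            float(r.t),
            float(r.lat),
            float(r.lon),
            None if pd.isna(r.acc) else float(r.acc),
        )
        for r in df.itertuples()
    ]
    return GpsTrack(fixes)


def write_gps_csv(track: GpsTrack, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "t": [f.t for f in track.fixes],
            "lat": [f.lat for f in track.fixes],
            "lon": [f.lon for f in track.fixes],
            "acc": [f.accuracy for f in track.fixes],
        }
    )
    df.to_csv(path, index=False, float_format="%.10f")


def read_gps_gpx(path: PathLike, hdop_to_meters: float = 5.0) -> GpsTrack:
    """Read a GPX 1.1 track.

    Times are converted to seconds from the first fix.  Horizontal
    accuracy is hdop (wherever a trkpt carries one, including inside
    extensions) times ``hdop_to_meters``; tracks without hdop get missing
    accuracies and a logged warning (the start gate is then skipped).
    """
    try:
        tree = etree.parse(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    pts = tree.findall(f".//{{{_GPX_NS}}}trkpt") or tree.findall(".//trkpt")
    if not pts:
        raise ParseError(f"{path}: no trkpt elements")
    raw = []
    for pt in pts:
        try:
            lat = float(pt.get("lat"))
            lon = float(pt.get("lon"))
        except (TypeError, ValueError):
            raise ParseError(f"{path}: trkpt at line {pt.sourceline} lacks lat/lon")
        time_el = pt.find(f"{{{_GPX_NS}}}time")
        if time_el is None:
            time_el = pt.find("time")
        if time_el is None or not time_el.text:
            raise ParseError(f"{path}: trkpt at line {pt.sourceline} lacks a time")
        try:
            when = _dt.datetime.fromisoformat(time_el.text.strip().replace("Z", "+00:00"))
        except ValueError as exc:
            raise ParseError(f"{path}: bad time at line {time_el.sourceline}: {exc}") from exc
        hdop = None
        for el in pt.iter():
            if etree.QName(el).localname == "hdop" and el.text:
                hdop = float(el.text)
                break
        raw.append((when, lat, lon, hdop))
    t0 = raw[0][0]
    if all(h is None for _, _, _, h in raw):
        logger.warning("%s: no hdop found; accuracies missing, start gate will be skipped", path)
    fixes = [
        GpsFix(
            (when - t0).total_seconds(),
            lat,
            lon,
            None if hdop is None else hdop * hdop_to_meters,
        )
        for when, lat, lon, hdop in raw
    ]
    return GpsTrack(fixes)


def write_gps_gpx(track: GpsTrack, path: PathLike, hdop_to_meters: float = 5.0) -> None:
    root = etree.Element("gpx", version="1.1", creator="remotefit", nsmap={None: _GPX_NS})
    seg = etree.SubElement(etree.SubElement(root, "trk"), "trkseg")
    for f in track.fixes:
        pt = etree.SubElement(seg, "trkpt", lat=f"{f.lat:.10f}", lon=f"{f.lon:.10f}")
        when = _GPX_EPOCH + _dt.timedelta(seconds=f.t)
        etree.SubElement(pt, "time").text = when.isoformat().replace("+00:00", "Z")
        if f.accuracy is not None:
            etree.SubElement(pt, "hdop").text = f"{f.accuracy / hdop_to_meters:.6f}"
    Path(path).write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )


# ---------------------------------------------------------------------------
# keypoints


def _check_joints(names) -> None:
    unknown = set(names) - set(COCO_JOINTS)
    if unknown:
        raise VocabularyError(f"joint name(s) outside the COCO-17 vocabulary: {sorted(unknown)}")


def read_keypoints_csv(path: PathLike) -> PoseSequence:
    """Read a long-form ``t,joint,x,y,conf`` CSV; absent joints get
    confidence 0 (PoseFrame fills them)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = {"t", "joint", "x", "y", "conf"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise ParseError(f"{path}: no keypoint rows")
    _check_joints(df["joint"].unique())
    frames = []
    for t, group in df.groupby("t", sort=True):
        kp = {
            r.joint: Keypoint(float(r.x), float(r.y), float(r.conf))
            for r in group.itertuples()
        }
        frames.append(PoseFrame(float(t), kp))
    ts = [f.t for f in frames]
    fps = 1.0 / (pd.Series(ts).diff().median()) if len(ts) > 1 else None
    return PoseSequence(frames, fps=fps)


def write_keypoints_csv(seq: PoseSequence, path: PathLike) -> None:
    rows = [
        {"t": f.t, "joint": name, "x": k.x, "y": k.y, "conf": k.confidence}
        for f in seq.frames
        for name, k in ((n, f[n]) for n in COCO_JOINTS)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_keypoints_json(path: PathLike) -> PoseSequence:
    """Read per-frame records [{"t": ..., "keypoints": {name: [x, y, conf]}}]."""
    try:
        records = json.loads(Path(path).read_text())
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(records, list) or not records:
        raise ParseError(f"{path}: expected a non-empty list of frame records")
    frames = []
    for rec in records:
        kps = rec.get("keypoints", {})
        _check_joints(kps.keys())
        frames.append(
            PoseFrame(
                float(rec["t"]),
                {name: Keypoint(float(x), float(y), float(c)) for name, (x, y, c) in kps.items()},
            )
        )
    frames.sort(key=lambda f: f.t)
    return PoseSequence(frames)


def write_keypoints_json(seq: PoseSequence, path: PathLike) -> None:
    records = [
        {
            "t": f.t,
            "keypoints": {n: [f[n].x, f[n].y, f[n].confidence] for n in COCO_JOINTS},
        }
        for f in seq.frames
    ]
    Path(path).write_text(json.dumps(records))


def read_keypoints(path: PathLike, format: Optional[str] = None) -> PoseSequence:
    fmt = format or ("json" if str(path).endswith(".json") else "csv")
    return read_keypoints_json(path) if fmt == "json" else read_keypoints_csv(path)


def read_gps(path: PathLike, format: Optional[str] = None, hdop_to_meters: float = 5.0) -> GpsTrack:
    fmt = format or ("gpx" if str(path).endswith(".gpx") else "csv")
    return read_gps_gpx(path, hdop_to_meters) if fmt == "gpx" else read_gps_csv(path)


# ---------------------------------------------------------------------------
# study tables


def read_study_csv(path: PathLike) -> pd.DataFrame:
    """Read a long study table.

    Required columns: subject, session, score_device.  Optional:
    score_gold, age, bmi, phone_brand, sex (device-only rows support
    reliability-only runs).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = {"subject", "session", "score_device"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_study_csv(rm: pd.DataFrame, pairs: pd.DataFrame, path: PathLike) -> None:
    """Merge a repeated-measures table and a paired table into the study
    CSV dialect (one row per subject x session)."""
    merged = rm.rename(columns={"score": "score_device"}).copy()
    if pairs is not None:
        gold = pairs[["subject", "session", "gold"]].rename(columns={"gold": "score_gold"})
        merged = merged.drop(columns=["score_device"]).merge(
            pairs[["subject", "session", "device", "gold"]].rename(
                columns={"device": "score_device", "gold": "score_gold"}
            ),
            on=["subject", "session"],
            how="left",
        )
    merged.to_csv(path, index=False, float_format="%.6f")


def study_to_repeated_measures(df: pd.DataFrame, score: str = "score_device") -> pd.DataFrame:
    """Project a study table onto the (subject, session, score, covariates)
    layout the reliability pipeline consumes."""
    if score not in df.columns:
        raise InvalidInputError(f"study table lacks column {score!r}")
    keep = [c for c in ("age", "bmi", "phone_brand", "sex") if c in df.columns]
    out = df[["subject", "session", score, *keep]].rename(columns={score: "score"})
    return out


def study_to_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Project a study table onto the paired device/gold layout."""
    if "score_gold" not in df.columns:
        raise InvalidInputError("study table has no score_gold column")
    out = df[["subject", "session", "score_device", "score_gold"]].rename(
        columns={"score_device": "device", "score_gold": "gold"}
    )
    return out.dropna(subset=["device", "gold"])
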