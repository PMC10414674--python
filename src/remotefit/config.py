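"""Centralized configuration.

All tunable thresholds of the walk engine, the sit-to-stand counter and the
statistics pipeline live here, with the defaults that the rest of the package
documents.  A plain ``key = value`` text file (keys ``section.name``) can
override any field; explicit CLI flags win over the file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import InvalidInputError


@dataclass
class WalkConfig:
    """6MWT engine thresholds.

    vmax_ms
        Hard ceiling on plausible walking speed; faster intervals are
        outliers (fast healthy walking tops out near 2.5 m/s, running
        starts above ~3 m/s, so 4.0 m/s is unambiguous).
    median_factor / outlier_window
        An interval is also an outlier when its speed exceeds
        ``median_factor`` times the median speed of the nearest
        ``outlier_window`` non-outlier intervals.
    gate_accuracy_m / gate_hold_s
        The start gate: horizontal accuracy must stay strictly below
        ``gate_accuracy_m`` for a contiguous ``gate_hold_s`` seconds.
    """

    fix_interval_s: float = 5.0
    vmax_ms: float = 4.0
    median_factor: float = 3.0
    outlier_window: int = 5
    gate_accuracy_m: float = 15.0
    gate_hold_s: float = 5.0
    test_duration_s: float = 360.0
    hdop_to_meters: float = 5.0


@dataclass
class StsConfig:
    """Sit-to-stand counter thresholds (angles in degrees, times in s)."""

    standing_angle: float = 160.0
    sitting_angle: float = 110.0
    keypoint_confidence: float = 0.3
    debounce_s: float = 0.2
    arm_radius_frac: float = 0.6     # of shoulder breadth, around chest proxy
    arm_hold_frac: float = 0.8       # fraction of transition frames with arms ok
    window_s: float = 30.0
    visibility_margin: float = 0.02  # image-border margin for the body check


@dataclass
class StatsConfig:
    """Measurement-properties pipeline settings."""

    alpha: float = 0.05
    ci_level: float = 0.95
    samplesize_k: int = 2


@dataclass
class ToolConfig:
    walk: WalkConfig = field(default_factory=WalkConfig)
    sts: StsConfig = field(default_factory=StsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "ToolConfig":
        """Parse a ``section.key = value`` text file into a ToolConfig."""
        cfg = cls()
        sections = {"walk": cfg.walk, "sts": cfg.sts, "stats": cfg.stats}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidInputError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key == "log_level":
                cfg.log_level = value
                continue
            if key == "seed":
                cfg.seed = int(value)
                continue
            if "." not in key:
                raise InvalidInputError(f"{path}:{lineno}: unknown key {key!r}")
            section, name = key.split(".", 1)
            target = sections.get(section)
            if target is None or name not in {f.name for f in dataclasses.fields(target)}:
                raise InvalidInputError(f"{path}:{lineno}: unknown key {key!r}")
            current = getattr(target, name)
            setattr(target, name, type(current)(value))
        return cfg
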