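"""Shipped schemas for the JSON reports the CLI writes.

Each schema maps a required key to the type(s) its value may take (None is
always admissible for optional quantities).  ``validate_report`` raises on
a missing key or a type mismatch, so tests and downstream consumers can
rely on the report layout.
"""

from __future__ import annotations

from .exceptions import InvalidInputError

_NUM = (int, float)

REPORT_SCHEMAS: dict[str, dict[str, tuple]] = {
    "walk": {
        "total_distance_m": _NUM,
        "raw_distance_m": _NUM,
        "n_intervals": (int,),
        "n_outliers": (int,),
        "predicted_m": _NUM + (type(None),),
        "percent_predicted": _NUM + (type(None),),
        "gate_time_s": _NUM + (type(None),),
    },
    "sts": {
        "correct": (int,),
        "incorrect": (int,),
        "events": (list,),
    },
    "validity": {
        "pearson_r": _NUM,
        "pearson_p": _NUM,
        "shapiro_p": _NUM,
        "ccc": _NUM,
        "ccc_ci": (list,),
        "mean_abs_rme_percent": _NUM,
        "bland_altman": (dict,),
        "grade_r": (str,),
        "grade_ccc": (str,),
        "n": (int,),
    },
    "reliability": {
        "icc": _NUM,
        "icc_ci": (list,),
        "var_between": _NUM,
        "var_error": _NUM,
        "sem": _NUM,
        "cv_percent": _NUM,
        "mdc": _NUM,
        "mdc_percent": _NUM,
        "grand_mean": _NUM,
        "model": (str,),
        "n_subjects": (int,),
        "n_sessions": (int,),
    },
}


def validate_report(kind: str, report: dict) -> None:
    schema = REPORT_SCHEMAS.get(kind)
    if schema is None:
        raise InvalidInputError(f"unknown report kind {kind!r}")
    for key, types in schema.items():
        if key not in report:
            raise InvalidInputError(f"{kind} report missing key {key!r}")
        if not isinstance(report[key], types):
            raise InvalidInputError(
                f"{kind} report key {key!r} has type {type(report[key]).__name__}"
            )
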