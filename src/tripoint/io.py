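"""CSV case files and the JSON analysis report.

Landmark files carry one digitized point per row in both image spaces:

    label,px,py,pz,rx,ry,rz

Implant files carry one endpoint per row:

    role,end,x,y,z        role in {planned, real}, end in {coronal, apical}

Coordinates are unitless in the file and interpreted as millimetres
(``# units=mm`` comment convention); lines starting with ``#`` are ignored.
"""

from __future__ import annotations

import csv
import json
import math
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

from .errors import CaseFormatError
from .geometry import Point3
from .indicators import SIGN_CONVENTION, compute_report
from .landmarks import LandmarkPair
from .registration import ImplantPose, register_case

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_implants",
    "write_implants",
    "run_analyze",
    "report_to_json",
    "summarize_reports",
]

LANDMARK_HEADER = ["label", "px", "py", "pz", "rx", "ry", "rz"]
IMPLANT_HEADER = ["role", "end", "x", "y", "z"]
REPORT_SCHEMA_VERSION = "1.0"

try:
    _VERSION = version("tripoint")
except PackageNotFoundError:  # pragma: no cover - source tree without install
    _VERSION = "unknown"


def _rows(path: Path):
    """Yield (line_number, row) skipping blanks and # comments."""
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            yield lineno, [cell.strip() for cell in row]


def _parse_float(cell: str, path: Path, lineno: int, column: str) -> float:
    try:
        value = float(cell)
    except ValueError:
        raise CaseFormatError(
            f"{path}:{lineno}: column {column!r} is not a number: {cell!r}"
        ) from None
    if not math.isfinite(value):
        raise CaseFormatError(
            f"{path}:{lineno}: column {column!r} is not finite: {cell!r}"
        )
    return value


def read_landmarks(path: str | Path) -> list[LandmarkPair]:
    """Read landmark pairs, rejecting malformed rows and duplicate labels."""
    path = Path(path)
    pairs: list[LandmarkPair] = []
    seen: dict[str, int] = {}
    header_seen = False
    for lineno, row in _rows(path):
        if not header_seen:
            if row != LANDMARK_HEADER:
                raise CaseFormatError(
                    f"{path}:{lineno}: expected header "
                    f"{','.join(LANDMARK_HEADER)!r}, got {','.join(row)!r}"
                )
            header_seen = True
            continue
        if len(row) != 7:
            raise CaseFormatError(
                f"{path}:{lineno}: expected 7 columns, got {len(row)}"
            )
        label = row[0]
        if not label:
            raise CaseFormatError(f"{path}:{lineno}: empty landmark label")
        if label in seen:
            raise CaseFormatError(
                f"{path}:{lineno}: duplicate label {label!r} "
                f"(first seen on line {seen[label]})"
            )
        seen[label] = lineno
        vals = [
            _parse_float(cell, path, lineno, col)
            for cell, col in zip(row[1:], LANDMARK_HEADER[1:])
        ]
        pairs.append(
            LandmarkPair(
                label=label,
                p=Point3(vals[0], vals[1], vals[2], space="P"),
                r=Point3(vals[3], vals[4], vals[5], space="R"),
            )
        )
    if not header_seen:
        raise CaseFormatError(f"{path}:1: empty landmark file (missing header)")
    return pairs


def write_landmarks(path: str | Path, pairs: Sequence[LandmarkPair]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        fh.write("# units=mm\n")
        writer.writerow(LANDMARK_HEADER)
        for pair in pairs:
            writer.writerow(
                [
                    pair.label,
                    repr(pair.p.x), repr(pair.p.y), repr(pair.p.z),
                    repr(pair.r.x), repr(pair.r.y), repr(pair.r.z),
                ]
            )


def read_implants(path: str | Path) -> tuple[ImplantPose, ImplantPose]:
    """Read planned and real implant endpoints; both poses must be complete."""
    path = Path(path)
    points: dict[tuple[str, str], Point3] = {}
    header_seen = False
    for lineno, row in _rows(path):
        if not header_seen:
            if row != IMPLANT_HEADER:
                raise CaseFormatError(
                    f"{path}:{lineno}: expected header "
                    f"{','.join(IMPLANT_HEADER)!r}, got {','.join(row)!r}"
                )
            header_seen = True
            continue
        if len(row) != 5:
            raise CaseFormatError(
                f"{path}:{lineno}: expected 5 columns, got {len(row)}"
            )
        role, end = row[0], row[1]
        if role not in ("planned", "real"):
            raise CaseFormatError(
                f"{path}:{lineno}: role must be 'planned' or 'real', got {role!r}"
            )
        if end not in ("coronal", "apical"):
            raise CaseFormatError(
                f"{path}:{lineno}: end must be 'coronal' or 'apical', got {end!r}"
            )
        if (role, end) in points:
            raise CaseFormatError(f"{path}:{lineno}: duplicate row for {role}/{end}")
        vals = [
            _parse_float(cell, path, lineno, col)
            for cell, col in zip(row[2:], IMPLANT_HEADER[2:])
        ]
        space = "P" if role == "planned" else "R"
        points[(role, end)] = Point3(vals[0], vals[1], vals[2], space=space)
    if not header_seen:
        raise CaseFormatError(f"{path}:1: empty implant file (missing header)")
    for key in (("planned", "coronal"), ("planned", "apical"),
                ("real", "coronal"), ("real", "apical")):
        if key not in points:
            raise CaseFormatError(f"{path}: missing row for {key[0]}/{key[1]}")
    planned = ImplantPose(points[("planned", "coronal")], points[("planned", "apical")])
    real = ImplantPose(points[("real", "coronal")], points[("real", "apical")])
    return planned, real


def write_implants(path: str | Path, planned: ImplantPose, real: ImplantPose) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        fh.write("# units=mm\n")
        writer.writerow(IMPLANT_HEADER)
        for role, pose in (("planned", planned), ("real", real)):
            for end, pt in (("coronal", pose.coronal), ("apical", pose.apical)):
                writer.writerow([role, end, repr(pt.x), repr(pt.y), repr(pt.z)])


def run_analyze(
    landmarks_path: str | Path,
    implants_path: str | Path,
    hs: float = 0.0,
    apply_hs_correction: bool = True,
) -> dict:
    """Full pipeline on one case: rank, register, correct, compute indicators.

    Returns the JSON-serialisable report dictionary.  Deterministic: identical
    inputs always produce identical reports.
    """
    pairs = read_landmarks(landmarks_path)
    planned, real = read_implants(implants_path)
    result = register_case(pairs, planned, real)
    report = compute_report(
        result.planned_in_N,
        result.real_in_N,
        hs=hs,
        apply_hs_correction=apply_hs_correction,
        system_error_mm=result.system_error_mm,
    )
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool": f"tripoint {_VERSION}",
        "sign_convention": SIGN_CONVENTION,
        "n_landmarks": len(pairs),
        "basic_triple": list(result.ranking.basic_triple),
        "elimination_order": list(result.ranking.elimination_order),
        "fourth_pair": result.ranking.fourth_pair,
        "point_errors": {k: v for k, v in result.ranking.point_errors.items()},
        "residuals_mm": dict(result.residuals_mm),
        "system_error_mm": result.system_error_mm,
        "hs_correction_applied": apply_hs_correction and hs > 0,
        "indicators": report.as_dict(),
    }


def summarize_reports(reports: Sequence[dict]):
    """Cohort mean +/- SD per indicator over a batch of case reports.

    Returns a pandas DataFrame indexed by indicator with columns ``mean``,
    ``sd``, ``min``, ``max`` and ``n`` (sample SD, ddof=1).
    """
    import pandas as pd

    rows = []
    for rep in reports:
        row = dict(rep["indicators"])
        row["system_error_mm"] = rep["system_error_mm"]
        rows.append(row)
    frame = pd.DataFrame(rows).astype(float)
    summary = frame.agg(["mean", "std", "min", "max", "count"]).T
    summary.columns = ["mean", "sd", "min", "max", "n"]
    return summary


def report_to_json(report: dict, path: str | Path | None = None) -> str:
    text = json.dumps(report, indent=2, sort_keys=False)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text
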