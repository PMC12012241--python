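"""Quantitative comparison of automated (L1, L2) and manual trajectories.

Per case, the planner is scored against the surgeon's plan by (a) the
angle between the two paths' directed entry->target vectors, in [0, 180]
degrees (directed, so anti-aligned plans score near 180 rather than
folding back under 90), (b) the Euclidean distance between the target
points, and (c) the perpendicular distance from the automated target to
the manual line.  Across cases the report carries means, sample standard
deviations (n-1) and paired t-tests between the L1 and L2 columns.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, fields

import numpy as np
from scipy import stats

from .axis_analysis import Trajectory

__all__ = [
    "CaseComparison",
    "ComparisonReport",
    "angle_between_paths",
    "target_distance",
    "point_to_line_distance",
    "compare_case",
    "summarize",
    "paired_t_test",
    "write_report",
    "read_report_json",
]

METRIC_FIELDS = (
    "angle_L1_deg",
    "angle_L2_deg",
    "target_dist_L1_mm",
    "target_dist_L2_mm",
    "point_to_line_L1_mm",
    "point_to_line_L2_mm",
)


@dataclass(frozen=True)
class CaseComparison:
    case_id: str
    angle_L1_deg: float = math.nan
    angle_L2_deg: float = math.nan
    target_dist_L1_mm: float = math.nan
    target_dist_L2_mm: float = math.nan
    point_to_line_L1_mm: float = math.nan
    point_to_line_L2_mm: float = math.nan

    def __post_init__(self):
        for name in ("angle_L1_deg", "angle_L2_deg"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 180.0:
                raise ValueError(f"{name} must lie in [0, 180], got {v}")
        for name in METRIC_FIELDS[2:]:
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class ComparisonReport:
    cases: tuple[CaseComparison, ...]
    means: dict
    sds: dict
    paired_t: dict  # e.g. {"angle_L1_vs_L2": {"t":..., "p_two_sided":..., "n":...}}


def angle_between_paths(a: Trajectory, b: Trajectory) -> float:
    """Angle (degrees, [0, 180]) between the directed entry->target vectors."""
    d = float(np.dot(a.direction, b.direction))
    return math.degrees(math.acos(max(-1.0, min(1.0, d))))


def target_distance(a: Trajectory, b: Trajectory) -> float:
    """Euclidean distance (mm) between the two target points."""
    return float(np.linalg.norm(a.target - b.target))


def point_to_line_distance(p: np.ndarray, line: Trajectory) -> float:
    """Perpendicular distance from ``p`` to the infinite line through the
    trajectory's entry along its direction."""
    p = np.asarray(p, dtype=float)
    return float(np.linalg.norm(np.cross(p - line.entry, line.direction)))


def compare_case(
    case_id: str, manual: Trajectory, l1: Trajectory | None = None, l2: Trajectory | None = None
) -> CaseComparison:
    """All per-case metrics for one surgeon plan versus the automated plans."""
    vals = {}
    for name, traj in (("L1", l1), ("L2", l2)):
        if traj is None:
            continue
        vals[f"angle_{name}_deg"] = angle_between_paths(traj, manual)
        vals[f"target_dist_{name}_mm"] = target_distance(traj, manual)
        vals[f"point_to_line_{name}_mm"] = point_to_line_distance(traj.target, manual)
    return CaseComparison(case_id=case_id, **vals)


def paired_t_test(x, y) -> dict:
    """Paired two-sided t-test on matched samples.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = x - y`` and the n-1 sd;
    p from Student's t with n-1 degrees of freedom.  Identical pairs
    (zero-variance differences) are a degenerate input and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired test needs two equal-length 1D samples")
    n = len(x)
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate paired test: all differences identical")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return {"t": float(t), "p_two_sided": float(p), "n": n}


def _column(cases, name):
    col = np.array([getattr(c, name) for c in cases], dtype=float)
    return col[~np.isnan(col)]


def summarize(cases) -> ComparisonReport:
    """Means, sample sds and L1-vs-L2 paired t-tests over the case list.

    The sd is reported as None for a single case; a paired test is run
    only when both columns are complete, n >= 2 and the differences have
    nonzero variance.
    """
    cases = tuple(cases)
    if len(cases) < 1:
        raise ValueError("need at least one case")
    means, sds = {}, {}
    for name in METRIC_FIELDS:
        col = _column(cases, name)
        means[name] = float(col.mean()) if len(col) else None
        sds[name] = float(col.std(ddof=1)) if len(col) >= 2 else None

    paired = {}
    for metric, a, b in (
        ("angle_L1_vs_L2", "angle_L1_deg", "angle_L2_deg"),
        ("target_dist_L1_vs_L2", "target_dist_L1_mm", "target_dist_L2_mm"),
    ):
        xa = np.array([getattr(c, a) for c in cases], dtype=float)
        xb = np.array([getattr(c, b) for c in cases], dtype=float)
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        if ok.sum() >= 2 and np.std(xa[ok] - xb[ok], ddof=1) > 0:
            paired[metric] = paired_t_test(xa[ok], xb[ok])
    return ComparisonReport(cases=cases, means=means, sds=sds, paired_t=paired)


def write_report(report: ComparisonReport, path) -> None:
    """Write the report; ``.json`` gives a lossless JSON, anything else a
    CSV with per-case rows followed by mean/sd summary rows."""
    path = str(path)
    if path.endswith(".json"):
        obj = {
            "cases": [
                {f.name: (None if isinstance(getattr(c, f.name), float) and math.isnan(getattr(c, f.name)) else getattr(c, f.name)) for f in fields(c)}
                for c in report.cases
            ],
            "means": report.means,
            "sds": report.sds,
            "paired_t": report.paired_t,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", *METRIC_FIELDS])
        for c in report.cases:
            writer.writerow([c.case_id, *[getattr(c, m) for m in METRIC_FIELDS]])
        writer.writerow(["mean", *[report.means[m] for m in METRIC_FIELDS]])
        writer.writerow(["sd", *[report.sds[m] for m in METRIC_FIELDS]])


def read_report_json(path) -> ComparisonReport:
    with open(path) as fh:
        obj = json.load(fh)
    cases = tuple(
        CaseComparison(**{k: (math.nan if v is None and k != "case_id" else v) for k, v in c.items()})
        for c in obj["cases"]
    )
    return ComparisonReport(cases=cases, means=obj["means"], sds=obj["sds"], paired_t=obj["paired_t"])
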