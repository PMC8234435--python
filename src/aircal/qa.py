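"""Weekly sensor quality-assurance flags.

Reproduces the logic of an automated weekly QA report for a sensor network:
each sensor is scored on four criteria — data completeness, departure from a
plausible signal range, collapsed daily variation, and correlation with the
nearest co-located/neighbouring sensor — at three severities (0 none, 1 warn,
2 severe), combined into a weighted priority score used to rank sensors for
replacement. Degrading any single criterion never decreases the priority.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

CRITERIA = ("completeness", "range", "variation", "correlation")


@dataclass
class QAThresholds:
    """Flagging thresholds; severity 1 = warn, 2 = severe.

    The criteria mirror the field report (completeness, plausible range,
    daily variation, neighbour correlation); the numeric cut-offs are
    configuration, with conservative defaults.
    """

    completeness_warn: float = 0.75   # fraction of expected samples
    completeness_severe: float = 0.50
    range_mv: tuple = (-100.0, 1000.0)  # plausible WE range, mV
    range_warn: float = 0.05          # fraction of samples outside range
    range_severe: float = 0.20
    quantization_mv: float = 0.1      # ADC step; variation floor is 2x this
    variation_warn_factor: float = 2.0
    correlation_warn: float = 0.5     # Pearson r with nearest neighbour
    correlation_severe: float = 0.2
    min_paired: int = 100             # pairs needed to assess correlation
    weights: Dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CRITERIA})


@dataclass
class FlagReport:
    """One sensor's QA outcome for one calendar week."""

    week: str                      # ISO week label, e.g. "2017-W22"
    sensor_id: str
    flags: Dict[str, int]          # criterion -> severity 0/1/2
    priority: float                # sum of weight * severity
    notes: Dict[str, str] = field(default_factory=dict)


def _iso_week(ts: pd.Timestamp) -> str:
    iso = ts.isocalendar()
    return f"{iso.year}-W{iso.week:02d}"


def _completeness_severity(frac: float, th: QAThresholds) -> int:
    if frac < th.completeness_severe:
        return 2
    if frac < th.completeness_warn:
        return 1
    return 0


def _range_severity(frac_out: float, th: QAThresholds) -> int:
    if frac_out > th.range_severe:
        return 2
    if frac_out > th.range_warn:
        return 1
    return 0


def _variation_severity(daily_sd: pd.Series, th: QAThresholds) -> int:
    floor = th.variation_warn_factor * th.quantization_mv
    if daily_sd.empty:
        return 0
    frac_low = float((daily_sd < floor).mean())
    if frac_low >= 0.5:
        return 2
    if frac_low > 0.0:
        return 1
    return 0


def _correlation_severity(r: Optional[float], th: QAThresholds) -> int:
    if r is None:
        return 0  # not assessable
    if r < th.correlation_severe:
        return 2
    if r < th.correlation_warn:
        return 1
    return 0


def weekly_flags(samples: pd.DataFrame,
                 neighbor_samples: Optional[pd.DataFrame] = None,
                 thresholds: Optional[QAThresholds] = None,
                 step_minutes: int = 5) -> List[FlagReport]:
    """Score one calendar week of 5-minute samples, per sensor.

    ``samples`` holds the week's raw records (columns as RawSample);
    ``neighbor_samples`` holds records from the nearest co-located or
    neighbouring monitor, matched by gas and timestamp for the correlation
    criterion. With no neighbour the correlation criterion is not assessable
    (severity 0). Deterministic given inputs.
    """
    th = thresholds or QAThresholds()
    if samples.empty:
        return []
    weeks = samples["timestamp"].map(_iso_week)
    if weeks.nunique() > 1:
        raise ValueError("weekly_flags expects one calendar week of samples, "
                         f"got {sorted(weeks.unique())}")
    week = weeks.iloc[0]
    expected = 7 * 24 * 60 // step_minutes

    reports: List[FlagReport] = []
    for sid, sub in samples.groupby("sensor_id", sort=True):
        flags: Dict[str, int] = {}
        notes: Dict[str, str] = {}

        frac = len(sub) / expected
        flags["completeness"] = _completeness_severity(frac, th)
        notes["completeness"] = f"{frac:.0%} of expected samples"

        lo, hi = th.range_mv
        frac_out = float(((sub["we_mv"] < lo) | (sub["we_mv"] > hi)).mean())
        flags["range"] = _range_severity(frac_out, th)
        notes["range"] = f"{frac_out:.1%} outside [{lo}, {hi}] mV"

        daily_sd = sub.groupby(sub["timestamp"].dt.floor("D"))["we_mv"].std(ddof=0)
        flags["variation"] = _variation_severity(daily_sd, th)

        r: Optional[float] = None
        if neighbor_samples is not None and not neighbor_samples.empty:
            gas = sub["gas"].iloc[0]
            nb = neighbor_samples[neighbor_samples["gas"] == gas]
            pair = sub.merge(nb[["timestamp", "we_mv"]], on="timestamp",
                             suffixes=("", "_nb"))
            if len(pair) >= th.min_paired:
                sd_a = pair["we_mv"].std()
                sd_b = pair["we_mv_nb"].std()
                if sd_a > 0 and sd_b > 0:
                    r = float(pair["we_mv"].corr(pair["we_mv_nb"]))
        flags["correlation"] = _correlation_severity(r, th)
        notes["correlation"] = ("not assessable" if r is None else f"r={r:.2f}")

        priority = float(sum(th.weights.get(c, 1.0) * flags[c] for c in CRITERIA))
        reports.append(FlagReport(week=week, sensor_id=str(sid), flags=flags,
                                  priority=priority, notes=notes))
    return reports


def reports_to_frame(reports: List[FlagReport]) -> pd.DataFrame:
    """Tabulate FlagReports for the per-week CSV output."""
    rows = []
    for r in reports:
        row = dict(week=r.week, sensor_id=r.sensor_id, priority=r.priority)
        for c in CRITERIA:
            row[f"flag_{c}"] = r.flags.get(c, 0)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("priority", ascending=False,
                                          kind="stable").reset_index(drop=True)


def summarize(reports: List[FlagReport]) -> str:
    """Human-readable weekly summary, highest priority first."""
    if not reports:
        return "no sensors reported this week\n"
    lines = [f"QA summary for week {reports[0].week}"]
    for r in sorted(reports, key=lambda x: -x.priority):
        flagged = ", ".join(f"{c}={s}" for c, s in r.flags.items() if s > 0)
        lines.append(f"  {r.sensor_id}: priority {r.priority:g}"
                     + (f" ({flagged})" if flagged else " (clean)"))
    return "\n".join(lines) + "\n"
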