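"""Raw-stream hygiene and aggregation.

Reads 5-minute sensor and reference streams, applies the study's exclusion
rules (8-hour post-relocation warm-up, event windows such as wildfire or
fireworks periods, flagged-malfunction spans), and averages to the hourly or
daily scale under a 75% completeness rule enforced at the native 5-minute
resolution: an hourly mean requires at least 9 of 12 five-minute samples, a
daily mean at least 216 of 288.

All timestamps are UTC; periods are labelled by their start; intervals are
half-open [start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import TARGET_GAS

logger = logging.getLogger(__name__)

WARMUP = pd.Timedelta(hours=8)

_SCALES = {
    "hourly": (pd.Timedelta(hours=1), "h"),
    "daily": (pd.Timedelta(days=1), "D"),
}


def native_records(samples: pd.DataFrame, step_minutes: int = 5) -> pd.DataFrame:
    """Recast exclusion-filtered 5-minute samples as native-scale records.

    No averaging: each sample becomes its own record (scale ``native``,
    n_valid 1), so calibration can run at the sensor's native resolution.
    """
    if "n_valid" in samples.columns or "timestamp" not in samples.columns:
        raise ValueError("input looks already aggregated")
    df = samples.rename(columns={"timestamp": "period"}).copy()
    df.insert(1, "scale", "native")
    df["n_valid"] = 1
    df.attrs["step_minutes"] = step_minutes
    return df


@dataclass(frozen=True)
class ExclusionWindow:
    """A closed-start, open-end span of data excluded for a stated reason."""

    start: pd.Timestamp
    end: pd.Timestamp
    reason: str = "event"  # warm-up | event | qa

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("ExclusionWindow requires start < end")


@dataclass(frozen=True)
class SensorFlag:
    """A sensor judged malfunctioning over [start, end)."""

    sensor_id: str
    start: pd.Timestamp
    end: pd.Timestamp


def _interval_of(samples: pd.DataFrame, schedule: pd.DataFrame) -> pd.DataFrame:
    """Attach the schedule interval covering each sample (NaT where none).

    Adds columns iv_start, iv_end, iv_location, iv_coloc.
    """
    out = []
    sched = schedule.sort_values("start")
    for mid, sub in samples.groupby("monitor_id", sort=False):
        ivs = sched[sched["monitor_id"] == mid]
        sub = sub.sort_values("timestamp")
        if ivs.empty:
            merged = sub.copy()
            merged["iv_start"] = pd.NaT
            merged["iv_end"] = pd.NaT
            merged["iv_location"] = None
            merged["iv_coloc"] = False
        else:
            merged = pd.merge_asof(
                sub, ivs[["start", "end", "location_id", "is_colocation"]],
                left_on="timestamp", right_on="start", direction="backward")
            inside = merged["timestamp"] < merged["end"]
            merged.loc[~inside, ["start", "end"]] = pd.NaT
            merged.loc[~inside, "location_id"] = None
            merged.loc[~inside, "is_colocation"] = False
            merged = merged.rename(columns={
                "start": "iv_start", "end": "iv_end",
                "location_id": "iv_location", "is_colocation": "iv_coloc"})
        out.append(merged)
    return pd.concat(out, ignore_index=True)


def apply_exclusions(samples: pd.DataFrame,
                     schedule: pd.DataFrame,
                     windows: Sequence[ExclusionWindow] = (),
                     flagged_sensors: Sequence[SensorFlag] = ()) -> pd.DataFrame:
    """Drop samples per the study's hygiene rules; log counts per reason.

    Removes, in order: samples not covered by any schedule interval
    ("unscheduled"), samples within 8 h after the start of their interval
    (warm-up after relocation), samples inside any exclusion window, and
    samples from sensors flagged malfunctioning during the flagged span.
    Idempotent: applying twice equals applying once.
    """
    if samples.empty:
        return samples.copy()
    df = _interval_of(samples, schedule)
    n0 = len(df)

    unscheduled = df["iv_start"].isna()
    warmup = ~unscheduled & (df["timestamp"] < df["iv_start"] + WARMUP)

    in_window = pd.Series(False, index=df.index)
    for w in windows:
        in_window |= (df["timestamp"] >= w.start) & (df["timestamp"] < w.end)

    flagged = pd.Series(False, index=df.index)
    for fl in flagged_sensors:
        flagged |= ((df["sensor_id"] == fl.sensor_id)
                    & (df["timestamp"] >= fl.start) & (df["timestamp"] < fl.end))

    drop = unscheduled | warmup | in_window | flagged
    counts = dict(unscheduled=int(unscheduled.sum()),
                  warmup=int((warmup & ~unscheduled).sum()),
                  window=int((in_window & ~unscheduled & ~warmup).sum()),
                  flagged=int((flagged & ~unscheduled & ~warmup & ~in_window).sum()))
    logger.info("apply_exclusions: kept %d of %d samples; removed %s",
                int((~drop).sum()), n0, counts)
    keep = df.loc[~drop, samples.columns]
    return keep.reset_index(drop=True)


def _completeness_threshold(scale: str, step_minutes: int) -> int:
    period, _ = _SCALES[scale]
    expected = int(period / pd.Timedelta(minutes=step_minutes))
    # 75% completeness at the native resolution: 9 of 12 hourly, 216 of 288 daily
    return int(np.ceil(0.75 * expected))


def aggregate(samples: pd.DataFrame, scale: str,
              step_minutes: int = 5) -> pd.DataFrame:
    """Average exclusion-filtered 5-minute samples to hourly or daily records.

    A record is emitted only when at least 75% of the expected native samples
    in the period are present (>= 9/12 hourly, >= 216/288 daily at 5-min step).
    Means are arithmetic over the valid samples. Raises if the input looks
    already aggregated, or if one (monitor, gas, period) key mixes sensor IDs.
    """
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {sorted(_SCALES)}, got {scale!r}")
    if "n_valid" in samples.columns or "timestamp" not in samples.columns:
        raise ValueError("input looks already aggregated; aggregate() expects "
                         "raw 5-minute samples")
    _, floor_freq = _SCALES[scale]
    thresh = _completeness_threshold(scale, step_minutes)

    df = samples.copy()
    df["period"] = df["timestamp"].dt.floor(floor_freq)

    mixed = (df.groupby(["monitor_id", "gas", "period"], observed=True)["sensor_id"]
               .nunique())
    if (mixed > 1).any():
        bad = mixed[mixed > 1].index[0]
        raise ValueError(f"mixed sensor_ids within aggregation key {bad}; "
                         "upstream keying bug")

    grouped = df.groupby(["monitor_id", "sensor_id", "gas", "period"], observed=True)
    agg = grouped.agg(we_mv=("we_mv", "mean"), aux_mv=("aux_mv", "mean"),
                      temp_c=("temp_c", "mean"), rh_pct=("rh_pct", "mean"),
                      n_valid=("we_mv", "size")).reset_index()
    agg = agg[agg["n_valid"] >= thresh].reset_index(drop=True)
    agg.insert(1, "scale", scale)
    return agg


def aggregate_reference(reference: pd.DataFrame, scale: str,
                        step_minutes: int = 5) -> pd.DataFrame:
    """Average reference concentrations to the same scale and completeness rule.

    Input columns: timestamp, site_id, gas, conc_ppb. Output: period, site_id,
    gas, conc_ppb, n_valid. Scale ``native`` passes samples through unaveraged.
    """
    if scale == "native":
        df = reference.rename(columns={"timestamp": "period"}).copy()
        df["n_valid"] = 1
        return df
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {sorted(_SCALES)}, got {scale!r}")
    _, floor_freq = _SCALES[scale]
    thresh = _completeness_threshold(scale, step_minutes)
    df = reference.copy()
    df["period"] = df["timestamp"].dt.floor(floor_freq)
    agg = (df.groupby(["site_id", "gas", "period"], observed=True)
             .agg(conc_ppb=("conc_ppb", "mean"), n_valid=("conc_ppb", "size"))
             .reset_index())
    return agg[agg["n_valid"] >= thresh].reset_index(drop=True)


def match_reference(averaged: pd.DataFrame,
                    reference: pd.DataFrame,
                    schedule: pd.DataFrame,
                    step_minutes: int = 5) -> pd.DataFrame:
    """Attach reference concentrations to co-located averaged records.

    A record is co-located when its whole period lies inside a co-location
    interval of its monitor; only such records receive the reference value of
    the sensor's target gas at that site and period (exact period alignment).
    Records at non-co-located times keep ``coloc=False`` and ``ref_ppb=NaN``.
    Co-located periods with no reference value are left unmatched and counted.

    ``reference`` must already be aggregated at the same scale (period labels
    equal). Returns the input with added columns site_id, coloc, ref_ppb.
    """
    if averaged.empty:
        out = averaged.copy()
        out["site_id"] = None
        out["coloc"] = False
        out["ref_ppb"] = np.nan
        return out
    scale = averaged["scale"].iloc[0]
    if scale == "native":
        period_len = pd.Timedelta(minutes=step_minutes)
    else:
        period_len, _ = _SCALES[scale]

    coloc_ivs = schedule[schedule["is_colocation"]].sort_values("start")
    parts = []
    for mid, sub in averaged.groupby("monitor_id", sort=False):
        ivs = coloc_ivs[coloc_ivs["monitor_id"] == mid]
        sub = sub.sort_values("period")
        if ivs.empty:
            sub = sub.copy()
            sub["site_id"] = None
            sub["coloc"] = False
        else:
            sub = pd.merge_asof(sub, ivs[["start", "end", "location_id"]],
                                left_on="period", right_on="start",
                                direction="backward")
            inside = sub["period"] + period_len <= sub["end"]
            sub["site_id"] = sub["location_id"].where(inside, None)
            sub["coloc"] = inside.fillna(False).astype(bool)
            sub = sub.drop(columns=["start", "end", "location_id"])
        parts.append(sub)
    df = pd.concat(parts, ignore_index=True)

    df["target_gas"] = df["gas"].map(TARGET_GAS)
    ref = reference.rename(columns={"gas": "target_gas"})
    df = df.merge(ref[["site_id", "target_gas", "period", "conc_ppb"]],
                  on=["site_id", "target_gas", "period"], how="left")
    df = df.rename(columns={"conc_ppb": "ref_ppb"}).drop(columns=["target_gas"])

    unmatched = int((df["coloc"] & df["ref_ppb"].isna()).sum())
    if unmatched:
        logger.warning("match_reference: %d co-located records had no reference "
                       "value at their period", unmatched)
    return df


# ---------------------------------------------------------------------------
# CSV I/O (formats shared with the synthetic generator)
# ---------------------------------------------------------------------------

def read_raw_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return df


def read_reference_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])


def read_schedule_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["start", "end"])


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
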