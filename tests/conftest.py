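"""Shared fixtures: compact synthetic deployments reused across test modules."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

import aircal as ac

logging.getLogger("aircal").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cfg() -> ac.SimConfig:
    """A 6-monitor, 45-day deployment at one agency site."""
    return ac.SimConfig(n_monitors=6, n_sites=1, duration_days=45,
                        coloc_fraction=0.30, seed=42)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """(truth, sensors, schedule, raw, reference) for the small deployment."""
    return ac.simulate_world(small_cfg)


@pytest.fixture(scope="session")
def hourly_tables(small_cfg, small_world):
    """Calibration tables (hourly) for every sensor type, plus specs."""
    truth, sensors, sched, raw, ref = small_world
    clean = ac.apply_exclusions(raw, sched)
    ref_h = ac.aggregate_reference(ref, "hourly")
    tables = {}
    for st in ac.SENSOR_TYPES:
        avg = ac.aggregate(clean[clean["gas"] == st], "hourly")
        tables[st] = ac.match_reference(avg, ref_h, sched)
    specs = ac.sensor_specs(sensors)
    return tables, specs


@pytest.fixture(scope="session")
def coloc_tables(hourly_tables):
    """Hourly tables restricted to co-located rows with reference values."""
    tables, specs = hourly_tables
    out = {st: t[t["coloc"] & t["ref_ppb"].notna()].reset_index(drop=True)
           for st, t in tables.items()}
    return out, specs


def make_clean_world(n_monitors=3, duration_days=30, seed=0, *,
                     noise=True, drift=False, environment=False,
                     common_gain=False, coloc_fraction=0.6,
                     sensor_overrides=None):
    """A configurable world for recovery tests.

    ``environment=False`` zeroes temperature/RH coefficients; ``drift=False``
    zeroes WE and Aux drift; ``common_gain`` gives every sensor the nominal
    sensitivity and gain. ``sensor_overrides`` is an optional callable applied
    to each SensorTruth after construction.
    """
    cfg = ac.SimConfig(n_monitors=n_monitors, duration_days=duration_days,
                       coloc_fraction=coloc_fraction, seed=seed)
    if not noise:
        cfg.noise_sd = {st: 0.0 for st in ac.SENSOR_TYPES}
    truth = ac.simulate_truth(cfg)
    sensors = ac.make_sensors(cfg)
    for s in sensors:
        if not environment:
            s.temp_coef = s.temp_quad_coef = s.rh_coef = 0.0
        if not drift:
            s.drift_slope = s.drift_aux_slope = 0.0
        if common_gain:
            s.sensitivity = ac.synthetic.NOMINAL_SENSITIVITY[s.sensor_type]
            s.gain = ac.synthetic.NOMINAL_GAIN
        if sensor_overrides is not None:
            sensor_overrides(s)
    sched = ac.make_schedule(cfg)
    raw = ac.simulate_signals(truth, sensors, sched, seed=cfg.seed + 2,
                              noise_sd=cfg.noise_sd)
    ref = ac.make_reference(truth, cfg)
    return cfg, truth, sensors, sched, raw, ref


def build_tables(cfg, raw, ref, sched, scale="hourly", coloc_only=False):
    """Exclusion-filter, aggregate and reference-match a raw world."""
    from aircal import ingest

    clean = ac.apply_exclusions(raw, sched)
    if scale == "native":
        avg_all = ingest.native_records(clean, cfg.step_minutes)
    else:
        avg_all = None
    ref_avg = ac.aggregate_reference(ref, scale, cfg.step_minutes)
    tables = {}
    for st in ac.SENSOR_TYPES:
        if scale == "native":
            avg = avg_all[avg_all["gas"] == st]
        else:
            avg = ac.aggregate(clean[clean["gas"] == st], scale, cfg.step_minutes)
        t = ac.match_reference(avg, ref_avg, sched, cfg.step_minutes)
        if coloc_only:
            t = t[t["coloc"] & t["ref_ppb"].notna()].reset_index(drop=True)
        tables[st] = t
    return tables
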