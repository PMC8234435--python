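"""Synthetic sensor-network generator with known ground truth.

Emulates a network of low-cost monitors (LCMs), each housing four Alphasense-style
electrochemical gas sensors (CO-B4, NO-B4, NO2-B43F, OX-B431), deployed on a
rotation schedule with anchor monitors permanently co-located at regulatory
("agency") sites and the rest briefly co-located between residential stints.

The latent truth process is deliberately minimal but keeps the structure the
calibration exploits:

* CO, NO and NO2 load on a shared lognormal "traffic" factor (AR(1) in time),
  giving pairwise correlations near ``traffic_corr``;
* O3 is anticorrelated with NO at the 5-minute scale and peaks in the afternoon;
* temperature and RH have seasonal + diurnal structure and confound the working
  electrode linearly plus a mild quadratic;
* each sensor carries its own zero offsets, gain, environmental coefficients and
  a linear baseline drift (ppb/year) that the auxiliary electrode only partly
  shares.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Target gases, in the order the calibration chain runs.
GASES: Tuple[str, ...] = ("CO", "NO", "NO2", "O3")

#: Electrochemical sensor types; OX responds to NO2 + O3 and its target gas is O3.
SENSOR_TYPES: Tuple[str, ...] = ("CO", "NO", "NO2", "OX")

#: Target (reference) gas for each sensor type.
TARGET_GAS: Dict[str, str] = {"CO": "CO", "NO": "NO", "NO2": "NO2", "OX": "O3"}

#: Cross-sensitivity of each sensor type to each gas (unitless, relative to target).
CROSS_SENS: Dict[str, Dict[str, float]] = {
    "CO": {"CO": 1.0},
    "NO": {"NO": 1.0},
    "NO2": {"NO2": 1.0, "O3": 0.0},  # O3 filter on the NO2 sensor
    "OX": {"NO2": 1.0, "O3": 1.0},
}

#: Nominal sensitivity (mV/ppb) per sensor type.
NOMINAL_SENSITIVITY: Dict[str, float] = {"CO": 0.45, "NO": 0.50, "NO2": 0.35, "OX": 0.40}
NOMINAL_GAIN: float = 0.8

#: Simulation epoch (arbitrary fixed origin for the deployment clock).
EPOCH = pd.Timestamp("2017-05-01T00:00:00Z")

MINUTES_PER_YEAR = 365.0 * 24 * 60


class ConfigurationError(ValueError):
    """A SimConfig (or derived request) is invalid; the message names the field."""


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------

def _default_gas_means() -> Dict[str, float]:
    return {"CO": 223.0, "NO": 6.0, "NO2": 11.0, "O3": 20.0}


def _default_gas_sd() -> Dict[str, float]:
    # 5-minute-scale marginal SDs; short-term variability runs well above the
    # daily-average SDs of an urban-background site
    return {"CO": 110.0, "NO": 12.0, "NO2": 8.0, "O3": 10.0}


def _default_diurnal_amp() -> Dict[str, float]:
    return {"CO": 50.0, "NO": 5.0, "NO2": 4.0, "O3": 8.0}


def _default_noise_sd() -> Dict[str, float]:
    # Manufacturer noise figures are quoted as +/- 2 SD in ppb; these are 1-SD
    # values at the native 5-minute scale.
    return {"CO": 2.0, "NO": 7.5, "NO2": 6.0, "OX": 2.0}


@dataclass
class SimConfig:
    """Study conditions for the synthetic world.

    Defaults describe a scaled-down deployment: 10 monitors, one agency site,
    180 days, ambient levels typical of an urban-background site, and sensor
    noise at the manufacturer-quoted magnitudes.
    """

    n_monitors: int = 10
    n_sites: int = 1
    duration_days: int = 180
    step_minutes: int = 5
    gas_means: Dict[str, float] = field(default_factory=_default_gas_means)
    gas_sd: Dict[str, float] = field(default_factory=_default_gas_sd)
    gas_diurnal_amp: Dict[str, float] = field(default_factory=_default_diurnal_amp)
    traffic_corr: float = 0.7
    temp_range: Tuple[float, float] = (0.0, 26.0)
    rh_range: Tuple[float, float] = (45.0, 100.0)
    noise_sd: Dict[str, float] = field(default_factory=_default_noise_sd)
    drift_sd: float = 5.0  # ppb/year, SD of per-sensor baseline drift slopes
    coloc_fraction: float = 0.20
    site_offset_frac: float = 0.15  # SD of residential site offsets, fraction of mean
    seed: int = 0

    def validate(self) -> None:
        if self.n_monitors < 1:
            raise ConfigurationError("n_monitors must be >= 1")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.n_monitors < self.n_sites:
            raise ConfigurationError("n_monitors must be >= n_sites (one anchor per site)")
        if self.duration_days < 1:
            raise ConfigurationError("duration_days must be >= 1")
        if self.step_minutes <= 0 or 60 % self.step_minutes != 0:
            raise ConfigurationError("step_minutes must be a positive divisor of 60")
        if not (0.0 < self.coloc_fraction <= 1.0):
            raise ConfigurationError("coloc_fraction must lie in (0, 1]")
        for name, m in (("gas_means", self.gas_means), ("gas_sd", self.gas_sd),
                        ("gas_diurnal_amp", self.gas_diurnal_amp)):
            for g in GASES:
                if g not in m:
                    raise ConfigurationError(f"{name} missing entry for {g}")
                if m[g] < 0:
                    raise ConfigurationError(f"{name}[{g}] must be >= 0")
        for st in SENSOR_TYPES:
            if st not in self.noise_sd:
                raise ConfigurationError(f"noise_sd missing entry for {st}")
            if self.noise_sd[st] < 0:
                raise ConfigurationError(f"noise_sd[{st}] must be >= 0")
        if not (0.0 <= self.traffic_corr <= 1.0):
            raise ConfigurationError("traffic_corr must lie in [0, 1]")
        if self.temp_range[0] >= self.temp_range[1]:
            raise ConfigurationError("temp_range must be ordered (low, high)")
        if self.rh_range[0] >= self.rh_range[1]:
            raise ConfigurationError("rh_range must be ordered (low, high)")
        if self.drift_sd < 0:
            raise ConfigurationError("drift_sd must be >= 0")

    @property
    def n_steps(self) -> int:
        return self.duration_days * 24 * 60 // self.step_minutes

    def site_ids(self) -> List[str]:
        return [f"site_{i}" for i in range(self.n_sites)]

    def residential_ids(self) -> List[str]:
        return [f"res_{i}" for i in range(max(0, self.n_monitors - self.n_sites))]


@dataclass
class SensorTruth:
    """Ground-truth physical parameters of one electrochemical sensor."""

    sensor_id: str
    monitor_id: str
    sensor_type: str  # one of SENSOR_TYPES
    V0_WE: float  # mV, working-electrode zero offset
    V0_Aux: float  # mV, auxiliary-electrode zero offset
    sensitivity: float  # mV/ppb
    gain: float  # unitless electronic gain
    temp_coef: float  # mV/degC on the WE
    temp_quad_coef: float  # mV/degC^2 mild curvature, centred at 13 degC
    rh_coef: float  # mV/%RH on the WE
    drift_slope: float  # ppb/year baseline drift on the WE
    drift_aux_slope: float  # ppb/year aging seen by the Aux electrode
    cross_sens: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ConfigurationError("sensitivity must be > 0")
        if self.gain <= 0:
            raise ConfigurationError("gain must be > 0")
        if not self.cross_sens:
            self.cross_sens = dict(CROSS_SENS[self.sensor_type])

    @property
    def gas(self) -> str:
        """Target gas this sensor is calibrated against."""
        return TARGET_GAS[self.sensor_type]


@dataclass
class TruthSeries:
    """Latent truth at every location: concentrations (ppb), temp (degC), RH (%).

    ``frame`` is long-format with columns: location_id, timestamp, CO, NO, NO2,
    O3, temp_c, rh_pct, on a regular grid of ``step_minutes``.
    """

    frame: pd.DataFrame
    step_minutes: int

    def locations(self) -> List[str]:
        return list(self.frame["location_id"].unique())

    def at(self, location_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["location_id"] == location_id]
        if sub.empty:
            raise KeyError(f"no truth series for location {location_id!r}")
        return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# latent truth process
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary standard-normal AR(1) path of length n (vectorised)."""
    from scipy.signal import lfilter

    e = rng.standard_normal(n)
    e[0] /= np.sqrt(1.0 - phi * phi)  # stationary start
    x = lfilter([1.0], [1.0, -phi], e * np.sqrt(1.0 - phi * phi))
    return x


def simulate_truth(config: SimConfig) -> TruthSeries:
    """Generate latent concentration/environment series for every location.

    CO, NO and NO2 share a lognormal traffic factor so their pairwise
    correlations sit near ``config.traffic_corr``; O3 is negatively correlated
    with NO. Residential locations reuse the regional process with constant
    site-level offsets. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_steps
    step = config.step_minutes

    times = EPOCH + pd.to_timedelta(np.arange(n) * step, unit="m")
    hour = (np.arange(n) * step / 60.0) % 24.0
    elapsed_days = np.arange(n) * step / 60.0 / 24.0
    # slow ("seasonal") cycle spanning the full configured environment ranges
    # within the simulated window: annual for long runs, one cycle otherwise
    season_period = min(365.0, float(config.duration_days))
    seasonal = np.cos(2 * np.pi * elapsed_days / season_period - np.pi)

    # AR(1) coefficients for the chosen step: traffic decays over ~3 h, O3 over ~8 h
    phi_traffic = float(np.exp(-step / 180.0))
    phi_o3 = float(np.exp(-step / 480.0))

    # shared lognormal traffic factor, standardised to mean 0 / var 1
    z = _ar1(rng, n, phi_traffic)
    raw = np.exp(0.6 * z)
    f = (raw - raw.mean()) / (raw.std() if raw.std() > 0 else 1.0)

    rho = config.traffic_corr
    diurnal_traffic = np.cos(2 * np.pi * (hour - 8.0) / 24.0)
    diurnal_o3 = np.cos(2 * np.pi * (hour - 15.0) / 24.0)

    dev: Dict[str, np.ndarray] = {}
    for g in ("CO", "NO", "NO2"):
        idio = _ar1(rng, n, phi_traffic)
        dev[g] = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * idio

    # O3: afternoon peak, anticorrelated with the NO stochastic component
    e_o3 = _ar1(rng, n, phi_o3)
    lam = 0.55
    dev["O3"] = -lam * dev["NO"] / max(dev["NO"].std(), 1e-12) + np.sqrt(1 - lam ** 2) * e_o3

    conc: Dict[str, np.ndarray] = {}
    for g in GASES:
        diurnal = diurnal_o3 if g == "O3" else diurnal_traffic
        series = (config.gas_means[g]
                  + config.gas_diurnal_amp[g] * diurnal
                  + config.gas_sd[g] * dev[g])
        conc[g] = np.clip(series, 0.0, None)

    # environment: seasonal + diurnal + AR noise, clipped into the configured range
    t_lo, t_hi = config.temp_range
    t_mid, t_span = 0.5 * (t_lo + t_hi), (t_hi - t_lo)
    diurnal_temp = np.cos(2 * np.pi * (hour - 15.0) / 24.0)
    temp = (t_mid + 0.30 * t_span * seasonal + 0.18 * t_span * diurnal_temp
            + 0.08 * t_span * _ar1(rng, n, phi_o3))
    temp = np.clip(temp, t_lo, t_hi)

    r_lo, r_hi = config.rh_range
    r_mid, r_span = 0.5 * (r_lo + r_hi), (r_hi - r_lo)
    rh = (r_mid - 0.25 * r_span * seasonal - 0.20 * r_span * diurnal_temp
          + 0.10 * r_span * _ar1(rng, n, phi_o3))
    rh = np.clip(np.clip(rh, r_lo, r_hi), 0.0, 100.0)

    frames = []
    locations = config.site_ids() + config.residential_ids()
    for loc in locations:
        if loc.startswith("res_"):
            offs = {g: rng.normal(0.0, config.site_offset_frac * config.gas_means[g])
                    for g in GASES}
            t_off = rng.normal(0.0, 1.0)
        else:
            offs = {g: 0.0 for g in GASES}
            t_off = 0.0
        df = pd.DataFrame({
            "location_id": loc,
            "timestamp": times,
            "temp_c": np.clip(temp + t_off, t_lo, t_hi),
            "rh_pct": rh,
        })
        for g in GASES:
            df[g] = np.clip(conc[g] + offs[g], 0.0, None)
        frames.append(df)

    frame = pd.concat(frames, ignore_index=True)
    return TruthSeries(frame=frame, step_minutes=step)


# ---------------------------------------------------------------------------
# deployment schedule
# ---------------------------------------------------------------------------

def make_schedule(config: SimConfig) -> pd.DataFrame:
    """Build a rotation schedule: anchors at agency sites, others rotating.

    One anchor monitor per agency site stays co-located the full duration.
    The remaining monitors alternate residential intervals with brief
    co-location visits, sized so the network-wide co-located fraction of
    monitor-days lands within +/-5 points of ``config.coloc_fraction``.

    Returns a DataFrame with columns monitor_id, location_id, start, end,
    is_colocation; intervals are half-open [start, end).
    """
    config.validate()
    start = EPOCH
    end = EPOCH + pd.Timedelta(days=config.duration_days)
    sites = config.site_ids()
    rows = []

    # anchors: monitors 0..n_sites-1, permanently co-located
    for i, site in enumerate(sites):
        rows.append(dict(monitor_id=f"m{i:02d}", location_id=site,
                         start=start, end=end, is_colocation=True))

    n_rot = config.n_monitors - config.n_sites
    if n_rot > 0:
        f = config.coloc_fraction
        f_rot = (f * config.n_monitors - config.n_sites) / n_rot
        if f_rot <= 0:
            raise ConfigurationError(
                "coloc_fraction infeasible: anchors alone exceed the target; "
                "raise coloc_fraction or reduce n_sites")
        if f_rot > 1:
            f_rot = 1.0
        cycle_days = min(28, config.duration_days)
        coloc_days = max(1, int(round(f_rot * cycle_days)))
        res_days = cycle_days - coloc_days
        if res_days < 0:
            raise ConfigurationError("coloc_fraction infeasible for this duration")
        for j in range(n_rot):
            mid = f"m{config.n_sites + j:02d}"
            home = f"res_{j}"
            site = sites[j % len(sites)]
            t = start
            while t < end:
                # within each cycle: residential stint first, then co-location visit
                cycle_start = t
                for kind, length in (("res", res_days), ("coloc", coloc_days)):
                    if length == 0:
                        continue
                    seg_start = cycle_start
                    seg_end = min(seg_start + pd.Timedelta(days=length), end)
                    if seg_start >= end:
                        break
                    rows.append(dict(
                        monitor_id=mid,
                        location_id=(home if kind == "res" else site),
                        start=seg_start, end=seg_end,
                        is_colocation=(kind == "coloc"),
                    ))
                    cycle_start = seg_end
                t = t + pd.Timedelta(days=cycle_days)

    sched = pd.DataFrame(rows)
    validate_schedule(sched)
    realized = colocated_fraction(sched)
    if abs(realized - config.coloc_fraction) > 0.05:
        logger.warning("realized co-location fraction %.3f misses target %.3f",
                       realized, config.coloc_fraction)
    return sched


def validate_schedule(schedule: pd.DataFrame) -> None:
    """Check the per-monitor non-overlap invariant; raise on violation."""
    for mid, sub in schedule.groupby("monitor_id"):
        sub = sub.sort_values("start")
        if (sub["end"].iloc[:-1].values > sub["start"].iloc[1:].values).any():
            raise ConfigurationError(f"overlapping intervals for monitor {mid}")
        if (sub["end"] <= sub["start"]).any():
            raise ConfigurationError(f"empty or inverted interval for monitor {mid}")


def colocated_fraction(schedule: pd.DataFrame) -> float:
    """Fraction of scheduled monitor-time spent co-located."""
    dur = (schedule["end"] - schedule["start"]).dt.total_seconds()
    total = dur.sum()
    return float(dur[schedule["is_colocation"]].sum() / total) if total else 0.0


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------

def make_sensors(config: SimConfig, rng: np.random.Generator | None = None) -> List[SensorTruth]:
    """Draw one sensor of each type per monitor, with realistic parameter spread."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    sensors = []
    for i in range(config.n_monitors):
        mid = f"m{i:02d}"
        for st in SENSOR_TYPES:
            sensors.append(SensorTruth(
                sensor_id=f"{mid}-{st}",
                monitor_id=mid,
                sensor_type=st,
                V0_WE=float(rng.normal(340.0, 25.0)),
                V0_Aux=float(rng.normal(335.0, 25.0)),
                # board gain is trimmed against the unit's measured sensitivity,
                # so the deployed mV/ppb spread is ~1%, not the raw-cell spread
                sensitivity=NOMINAL_SENSITIVITY[st] * float(1 + rng.normal(0, 0.01)),
                gain=NOMINAL_GAIN * float(1 + rng.normal(0, 0.01)),
                temp_coef=float(rng.normal(0.35, 0.03)),
                temp_quad_coef=float(rng.normal(0.004, 0.0005)),
                rh_coef=float(rng.normal(0.08, 0.01)),
                drift_slope=float(rng.normal(0.0, config.drift_sd)),
                drift_aux_slope=float(rng.normal(0.0, config.drift_sd / 2.0)),
            ))
    return sensors


# ---------------------------------------------------------------------------
# forward model: truth -> raw electrode signals
# ---------------------------------------------------------------------------

def simulate_signals(truth: TruthSeries,
                     sensors: Sequence[SensorTruth],
                     schedule: pd.DataFrame,
                     seed: int,
                     noise_sd: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Forward-model latent truth into raw WE/Aux signals under the schedule.

    WE(t) = V0_WE + s*g * sum_g cross_sens[g]*C_g(t) + temp_coef*T + rh_coef*RH
            + temp_quad*(T-13)^2 + s*g*drift_slope*t_years + noise
    Aux(t) = V0_Aux + s*g*drift_aux_slope*t_years + noise/4

    The Aux electrode sees aging but no gas or environment. Noise is Gaussian,
    ``noise_sd`` in ppb-equivalent units at the native step (converted to mV by
    s*g); the Aux noise is a quarter of the WE noise (electronics only).

    Returns a long DataFrame: timestamp, monitor_id, sensor_id, gas (sensor
    type), we_mv, aux_mv, temp_c, rh_pct. Scheduled intervals that extend
    beyond the truth grid are trimmed with a logged warning.
    """
    if noise_sd is None:
        noise_sd = _default_noise_sd()
    rng = np.random.default_rng(seed)
    validate_schedule(schedule)

    by_monitor: Dict[str, List[SensorTruth]] = {}
    for s in sensors:
        by_monitor.setdefault(s.monitor_id, []).append(s)

    # index truth per location once, by position on the regular grid
    loc_frames = {loc: truth.at(loc) for loc in truth.locations()}
    step = truth.step_minutes
    n_omitted = 0
    out = []

    for row in schedule.itertuples(index=False):
        if row.monitor_id not in by_monitor:
            continue
        if row.location_id not in loc_frames:
            raise ConfigurationError(
                f"scheduled location {row.location_id!r} has no truth series")
        lf = loc_frames[row.location_id]
        t0, t1 = lf["timestamp"].iloc[0], lf["timestamp"].iloc[-1]
        i0 = int(np.ceil((row.start - t0).total_seconds() / 60.0 / step))
        i1 = int(np.ceil((row.end - t0).total_seconds() / 60.0 / step))
        if i0 < 0 or i1 > len(lf):
            n_omitted += max(0, -i0) + max(0, i1 - len(lf))
            logger.warning("interval for %s at %s extends beyond truth grid; trimmed",
                           row.monitor_id, row.location_id)
            i0, i1 = max(i0, 0), min(i1, len(lf))
        if i1 <= i0:
            continue
        seg = lf.iloc[i0:i1]
        times = seg["timestamp"].to_numpy()
        t_years = ((seg["timestamp"] - EPOCH).dt.total_seconds() / 60.0
                   / MINUTES_PER_YEAR).to_numpy()
        temp = seg["temp_c"].to_numpy()
        rh = seg["rh_pct"].to_numpy()
        m = len(seg)

        for s in by_monitor[row.monitor_id]:
            sg = s.sensitivity * s.gain
            c_eff = np.zeros(m)
            for g, w in s.cross_sens.items():
                if w != 0.0:
                    c_eff = c_eff + w * seg[g].to_numpy()
            sigma = float(noise_sd.get(s.sensor_type, 0.0)) * sg
            we = (s.V0_WE + sg * c_eff
                  + s.temp_coef * temp
                  + s.temp_quad_coef * (temp - 13.0) ** 2
                  + s.rh_coef * rh
                  + sg * s.drift_slope * t_years)
            aux = s.V0_Aux + sg * s.drift_aux_slope * t_years
            if sigma > 0:
                we = we + rng.normal(0.0, sigma, m)
                aux = aux + rng.normal(0.0, sigma / 4.0, m)
            out.append(pd.DataFrame({
                "timestamp": times,
                "monitor_id": row.monitor_id,
                "sensor_id": s.sensor_id,
                "gas": s.sensor_type,
                "we_mv": we,
                "aux_mv": aux,
                "temp_c": temp,
                "rh_pct": rh,
            }))

    if n_omitted:
        logger.warning("omitted %d out-of-grid sample slots in total", n_omitted)
    if not out:
        return pd.DataFrame(columns=["timestamp", "monitor_id", "sensor_id", "gas",
                                     "we_mv", "aux_mv", "temp_c", "rh_pct"])
    return pd.concat(out, ignore_index=True)


def make_reference(truth: TruthSeries, config: SimConfig) -> pd.DataFrame:
    """Reference ("agency") concentrations at every agency site, 5-min scale.

    Returns columns: timestamp, site_id, gas, conc_ppb.
    """
    frames = []
    for site in config.site_ids():
        lf = truth.at(site)
        for g in GASES:
            frames.append(pd.DataFrame({
                "timestamp": lf["timestamp"],
                "site_id": site,
                "gas": g,
                "conc_ppb": lf[g].to_numpy(),
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_world(config: SimConfig):
    """Convenience: truth, sensors, schedule, raw signals and reference in one call.

    Returns (truth, sensors, schedule, raw, reference). All randomness derives
    from ``config.seed``.
    """
    truth = simulate_truth(config)
    sensors = make_sensors(config)
    schedule = make_schedule(config)
    raw = simulate_signals(truth, sensors, schedule, seed=config.seed + 2,
                           noise_sd=config.noise_sd)
    reference = make_reference(truth, config)
    return truth, sensors, schedule, raw, reference


def sensor_specs(sensors: Sequence[SensorTruth],
                 baseline_error_sd: float = 0.0,
                 seed: int = 0) -> pd.DataFrame:
    """Manufacturer-style spec sheet for a set of sensors.

    With ``baseline_error_sd`` > 0 the declared zero offsets are perturbed
    (in ppb-equivalent units), emulating spec-sheet baselines that disagree
    with the true sensor baseline — the situation the co-location offset
    algorithm corrects.

    Returns a DataFrame with columns sensor_id, gas, V0_WE, V0_Aux,
    sensitivity, gain (gas = sensor type).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in sensors:
        err_mv = rng.normal(0.0, baseline_error_sd) * s.sensitivity * s.gain \
            if baseline_error_sd > 0 else 0.0
        rows.append(dict(sensor_id=s.sensor_id, gas=s.sensor_type,
                         V0_WE=s.V0_WE + err_mv, V0_Aux=s.V0_Aux,
                         sensitivity=s.sensitivity, gain=s.gain))
    return pd.DataFrame(rows)
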