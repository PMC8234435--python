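"""Week-blocked cross-validation, drift estimation and residual diagnostics.

Model skill is measured with 10-fold cross-validation in which entire ISO
calendar weeks of co-located data are assigned to folds, so temporally
adjacent observations never straddle the train/test split — pointwise-random
CV is optimistic when errors are autocorrelated. Summary measures are the
pooled held-out RMSE and R^2 (1 - SSE/SST over all held-out rows).

Sensor baseline drift is estimated per sensor as the OLS slope of the final
model's co-located residuals against time, in ppb/year, restricted to sensors
co-located for at least one year and at least 20% of their deployment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import models as cm

logger = logging.getLogger(__name__)

SECONDS_PER_YEAR = 365.0 * 24 * 3600


def iso_week(ts: pd.Timestamp) -> str:
    """ISO-8601 calendar-week label, e.g. '2017-W22'."""
    iso = ts.isocalendar()
    return f"{iso.year}-W{iso.week:02d}"


def week_labels(periods: pd.Series) -> pd.Series:
    iso = periods.dt.isocalendar()
    return iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

@dataclass
class FoldMap:
    """Random balanced assignment of calendar weeks to folds 1..k."""

    assignment: Dict[str, int]
    k: int
    seed: int

    def fold_of(self, weeks: pd.Series) -> pd.Series:
        return weeks.map(self.assignment)


def assign_folds(weeks: Sequence[str], k: int = 10, seed: int = 0) -> FoldMap:
    """Randomly partition calendar weeks into k balanced folds.

    Fold sizes differ by at most one week; deterministic given the seed.
    """
    weeks = sorted(set(weeks))
    if len(weeks) < k:
        raise ValueError(
            f"only {len(weeks)} weeks with co-located data; need >= {k} "
            f"(use a smaller k)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(weeks))
    assignment = {weeks[j]: (i % k) + 1 for i, j in enumerate(order)}
    return FoldMap(assignment=assignment, k=k, seed=seed)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Pooled held-out performance for one gas and model."""

    gas: str                      # sensor type
    model_id: int
    cv_rmse: float
    cv_r2: float
    n: int
    fold_map: Optional[FoldMap]
    predictions: pd.DataFrame     # period, monitor_id, sensor_id, ref_ppb, pred_ppb, fold
    coverage: float = 1.0         # fraction of folds successfully evaluated
    blocked: bool = True

    def summary(self) -> Dict[str, float]:
        return dict(gas=self.gas, model_id=self.model_id, cv_rmse=self.cv_rmse,
                    cv_r2=self.cv_r2, n=self.n, coverage=self.coverage)


def _pooled_metrics(pred: pd.DataFrame):
    err = pred["pred_ppb"] - pred["ref_ppb"]
    sse = float((err ** 2).sum())
    n = len(pred)
    rmse = float(np.sqrt(sse / n)) if n else float("nan")
    sst = float(((pred["ref_ppb"] - pred["ref_ppb"].mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return rmse, r2, n


def cross_validate(tables: Mapping[str, pd.DataFrame],
                   gas: str,
                   model_ids: Mapping[str, int],
                   k: int = 10,
                   seed: int = 0,
                   blocked: bool = True,
                   specs: Optional[pd.DataFrame] = None,
                   bases: Optional[Dict[str, cm.BasisSpec]] = None,
                   offsets: Optional[Mapping[str, Mapping[str, float]]] = None,
                   copollutant_term: bool = True,
                   ) -> CVReport:
    """k-fold CV of one gas's calibration, refitting the chain inside each fold.

    ``tables`` holds the full calibration table per sensor type (the chain
    context); ``model_ids`` names the ladder model per sensor type, and must
    include every upstream stage the target model needs. In blocked mode whole
    calendar weeks go to folds; with ``blocked=False`` individual rows are
    randomly assigned (for quantifying the optimism blocking prevents). The
    blocking invariant — no held-out row's week in its training set — is
    asserted on every fold. Upstream co-pollutant fits are restricted to the
    same training rows to avoid leakage.
    """
    table = tables[gas]
    eligible = table["ref_ppb"].notna() & table["coloc"]
    rows = table[eligible]
    if rows.empty:
        raise ValueError(f"no co-located rows with reference data for {gas}")
    weeks = week_labels(rows["period"])

    if blocked:
        fold_map = assign_folds(weeks.unique(), k=k, seed=seed)
        folds = fold_map.fold_of(weeks)
    else:
        if len(rows) < k:
            raise ValueError(f"only {len(rows)} rows; need >= {k}")
        rng = np.random.default_rng(seed)
        fold_map = None
        folds = pd.Series((rng.permutation(len(rows)) % k) + 1, index=rows.index)

    held_out = []
    n_failed = 0
    for fold in range(1, k + 1):
        test_idx = rows.index[folds == fold]
        train_idx = rows.index[folds != fold]
        if len(test_idx) == 0:
            continue
        if blocked:
            train_weeks = set(week_labels(table.loc[train_idx, "period"]))
            test_weeks = set(week_labels(table.loc[test_idx, "period"]))
            leaked = train_weeks & test_weeks
            assert not leaked, f"blocking violated: weeks {sorted(leaked)} in both sets"

        # restrict every chain stage's training rows to the training periods
        if blocked:
            train_week_set = set(week_labels(table.loc[train_idx, "period"]))

            def stage_mask(t: pd.DataFrame) -> pd.Series:
                ok = t["ref_ppb"].notna() & t["coloc"]
                return ok & week_labels(t["period"]).isin(train_week_set)
        else:
            def stage_mask(t: pd.DataFrame) -> pd.Series:
                ok = t["ref_ppb"].notna() & t["coloc"]
                if t is table:
                    m = pd.Series(False, index=t.index)
                    m.loc[train_idx] = True
                    return ok & m
                return ok

        masks = {st: stage_mask(tables[st]) for st in model_ids}
        try:
            chain = cm.calibrate_chain(tables, model_ids, specs=specs,
                                       bases=bases, offsets=offsets,
                                       train_mask=masks,
                                       copollutant_term=copollutant_term,
                                       skip_unseen=True)
        except (cm.RankDeficientError, ValueError) as e:
            logger.warning("fold %d skipped: %s", fold, e)
            n_failed += 1
            continue

        pred = chain.predictions[gas].merge(
            table.loc[test_idx, ["period", "monitor_id", "sensor_id", "ref_ppb"]],
            on=["period", "monitor_id", "sensor_id"], how="inner")
        pred = pred.dropna(subset=["pred_ppb", "ref_ppb"])
        pred["fold"] = fold
        held_out.append(pred)

    if not held_out:
        raise RuntimeError("every CV fold failed")
    pooled = pd.concat(held_out, ignore_index=True)
    rmse, r2, n = _pooled_metrics(pooled)
    coverage = 1.0 - n_failed / k
    if coverage < 1.0:
        logger.warning("CV coverage %.0f%% (%d folds failed)", 100 * coverage, n_failed)
    return CVReport(gas=gas, model_id=model_ids[gas], cv_rmse=rmse, cv_r2=r2,
                    n=n, fold_map=fold_map, predictions=pooled,
                    coverage=coverage, blocked=blocked)


# ---------------------------------------------------------------------------
# drift estimation
# ---------------------------------------------------------------------------

@dataclass
class DriftEstimate:
    """Residual-slope drift for one sensor, in ppb per year."""

    sensor_id: str
    gas: str
    slope_ppb_per_year: float
    slope_se: float
    span_days: float
    coloc_fraction: float
    n: int
    eligible: bool


def estimate_drift(residuals: pd.DataFrame,
                   schedule: pd.DataFrame,
                   gas: str,
                   min_points: int = 30,
                   min_span_days: float = 365.0,
                   min_coloc_fraction: float = 0.20) -> List[DriftEstimate]:
    """Per-sensor OLS slope of calibration residuals against time.

    ``residuals`` needs columns sensor_id, monitor_id, period, resid_ppb
    (prediction minus reference on co-located periods, final model). The
    eligibility flag requires a co-location span of at least one year covering
    at least 20% of the sensor's deployment; sensors with fewer than
    ``min_points`` residuals are suppressed with a warning.
    """
    out: List[DriftEstimate] = []
    sched = schedule.copy()
    sched["dur"] = (sched["end"] - sched["start"]).dt.total_seconds()

    for sid, sub in residuals.groupby("sensor_id", sort=True):
        sub = sub.dropna(subset=["resid_ppb"])
        if len(sub) < min_points:
            logger.warning("drift for %s suppressed: only %d residuals", sid, len(sub))
            continue
        t_years = ((sub["period"] - sub["period"].min()).dt.total_seconds()
                   / SECONDS_PER_YEAR).to_numpy()
        r = sub["resid_ppb"].to_numpy(dtype=float)
        A = np.column_stack([np.ones_like(t_years), t_years])
        beta, *_ = np.linalg.lstsq(A, r, rcond=None)
        resid = r - A @ beta
        dof = max(len(r) - 2, 1)
        s2 = float(resid @ resid) / dof
        tt = float(((t_years - t_years.mean()) ** 2).sum())
        se = float(np.sqrt(s2 / tt)) if tt > 0 else float("inf")

        span_days = (sub["period"].max() - sub["period"].min()).total_seconds() / 86400.0
        mid = sub["monitor_id"].iloc[0]
        msched = sched[sched["monitor_id"] == mid]
        total = msched["dur"].sum()
        coloc = msched.loc[msched["is_colocation"], "dur"].sum()
        frac = float(coloc / total) if total > 0 else 0.0
        eligible = bool(span_days >= min_span_days and frac >= min_coloc_fraction)
        out.append(DriftEstimate(sensor_id=str(sid), gas=gas,
                                 slope_ppb_per_year=float(beta[1]),
                                 slope_se=se, span_days=float(span_days),
                                 coloc_fraction=frac, n=int(len(sub)),
                                 eligible=eligible))
    return out


def drift_table(estimates: List[DriftEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates])


def drift_summary(estimates: List[DriftEstimate]) -> Dict[str, float]:
    """Mean and range of drift slopes across eligible sensors."""
    el = [e.slope_ppb_per_year for e in estimates if e.eligible]
    if not el:
        return dict(n_eligible=0, mean=float("nan"),
                    low=float("nan"), high=float("nan"))
    return dict(n_eligible=len(el), mean=float(np.mean(el)),
                low=float(np.min(el)), high=float(np.max(el)))


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticTable:
    """Binned residual means and a loess smooth against one covariate."""

    covariate: str
    bins: pd.DataFrame            # bin_center, mean, se, n, smooth
    trend_flagged: bool
    frac_outside: float           # fraction of support where |smooth| > 2 SE


def residual_diagnostics(residuals: pd.DataFrame,
                         covariates: Sequence[str] = ("ref_ppb", "temp_c",
                                                      "rh_pct", "time"),
                         n_bins: int = 10,
                         flag_fraction: float = 0.20) -> Dict[str, DiagnosticTable]:
    """Binned means and a loess smooth of residuals per covariate.

    A systematic trend is flagged when the smooth leaves the +/-2 SE band over
    more than ``flag_fraction`` of the covariate's support. Empty input yields
    empty tables.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    out: Dict[str, DiagnosticTable] = {}
    df = residuals.dropna(subset=["resid_ppb"]).copy()
    if "time" in covariates and "period" in df.columns:
        t0 = df["period"].min()
        df["time"] = ((df["period"] - t0).dt.total_seconds() / 86400.0
                      if len(df) else np.nan)

    for cov in covariates:
        if df.empty or cov not in df.columns:
            out[cov] = DiagnosticTable(cov, pd.DataFrame(
                columns=["bin_center", "mean", "se", "n", "smooth"]), False, 0.0)
            continue
        sub = df.dropna(subset=[cov])
        if sub.empty:
            out[cov] = DiagnosticTable(cov, pd.DataFrame(
                columns=["bin_center", "mean", "se", "n", "smooth"]), False, 0.0)
            continue
        x = sub[cov].to_numpy(dtype=float)
        r = sub["resid_ppb"].to_numpy(dtype=float)
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1,
                      0, len(edges) - 2)
        rows = []
        for b in range(len(edges) - 1):
            m = idx == b
            nb = int(m.sum())
            if nb == 0:
                continue
            rows.append(dict(bin_center=float(x[m].mean()),
                             mean=float(r[m].mean()),
                             se=float(r[m].std(ddof=1) / np.sqrt(nb)) if nb > 1 else np.inf,
                             n=nb))
        bins = pd.DataFrame(rows)
        sm_xy = lowess(r, x, frac=2.0 / 3.0, xvals=bins["bin_center"].to_numpy())
        bins["smooth"] = sm_xy
        outside = np.abs(bins["smooth"]) > 2.0 * bins["se"]
        frac_out = float(outside.mean()) if len(bins) else 0.0
        out[cov] = DiagnosticTable(cov, bins, bool(frac_out > flag_fraction),
                                   frac_out)
    return out
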