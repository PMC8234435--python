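"""Calibration model ladder for electrochemical gas sensors.

The ladder runs from the manufacturer's closed-form conversion (Model 0)
through increasingly rich ordinary-least-squares regressions of the reference
concentration on raw electrode signals:

* Model 0 — manufacturer conversion: [(WE - V0_WE) - (Aux - V0_Aux)] / (sensitivity * gain)
* Model 1 — WE, Aux, sensor-ID intercepts
* Model 2 — Model 1 + linear temperature and RH
* Model 3 — Model 2 + WE x temperature and WE x RH interactions
* Model 4 — sensor-ID intercepts, WE, Aux, degree-1 b-spline bases for
  temperature (interior knots 4, 21 degC) and RH (knot 60%), WE x basis
  interactions, and a calibrated co-pollutant term (NO2 model adds calibrated
  CO; O3 model adds calibrated NO2)
* Model 5 — Model 4 + sensor-specific WE slopes
* Models 6/7 — Model 1/4 column sets with the net signal pre-shifted by a
  co-location baseline-offset solution and a single common intercept

Oxidising-gas cross-sensitivity is handled by the calibration chain: the O3
(OX sensor) model consumes the previously calibrated NO2 of the same monitor
and averaging period, and the NO2 model the previously calibrated CO, so fits
must run in the order CO -> NO -> NO2 -> O3.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline

from .synthetic import TARGET_GAS

logger = logging.getLogger(__name__)

#: Sensor types ordered so every co-pollutant dependency points backwards.
CHAIN_ORDER: Tuple[str, ...] = ("CO", "NO", "NO2", "OX")

#: Co-pollutant (by sensor type) each final model consumes: NO2 uses calibrated
#: CO, the OX (O3) model uses calibrated NO2.
COPOLLUTANT: Dict[str, Optional[str]] = {"CO": None, "NO": None, "NO2": "CO", "OX": "NO2"}

MODEL_IDS = tuple(range(8))


class RankDeficientError(np.linalg.LinAlgError):
    """The design matrix is rank deficient; message names collinear columns."""


class ChainOrderError(ValueError):
    """A co-pollutant fit was requested before its upstream stage."""


# ---------------------------------------------------------------------------
# Model 0: manufacturer conversion
# ---------------------------------------------------------------------------

def manufacturer_concentration(we_mv, aux_mv, spec: Mapping) -> np.ndarray:
    """Convert raw electrode signals to ppb with the manufacturer's terms.

    concentration = [(WE - V0_WE) - (Aux - V0_Aux)] / (sensitivity * gain).
    Negative values are permitted (and occur at low concentrations).
    ``spec`` needs keys V0_WE, V0_Aux, sensitivity, gain.
    """
    sg = float(spec["sensitivity"]) * float(spec["gain"])
    if sg == 0.0:
        raise ValueError("sensitivity * gain must be nonzero")
    net = (np.asarray(we_mv, dtype=float) - float(spec["V0_WE"])) \
        - (np.asarray(aux_mv, dtype=float) - float(spec["V0_Aux"]))
    return net / sg


def manufacturer_predictions(records: pd.DataFrame, specs: pd.DataFrame) -> pd.Series:
    """Model-0 predictions for a table of averaged records (any sensor mix)."""
    sp = specs.set_index("sensor_id")
    sg = records["sensor_id"].map(sp["sensitivity"] * sp["gain"]).to_numpy(dtype=float)
    if np.any(sg == 0.0) or np.any(~np.isfinite(sg)):
        raise ValueError("sensitivity * gain must be nonzero for every sensor")
    net = ((records["we_mv"] - records["sensor_id"].map(sp["V0_WE"]))
           - (records["aux_mv"] - records["sensor_id"].map(sp["V0_Aux"]))).to_numpy(dtype=float)
    return pd.Series(net / sg, index=records.index, name="pred_ppb")


# ---------------------------------------------------------------------------
# spline bases
# ---------------------------------------------------------------------------

@dataclass
class BasisSpec:
    """Degree-1 b-spline basis for one covariate, intercept column dropped.

    ``n_basis`` = n_interior_knots + degree columns after the drop; with the
    study knots this is 3 for temperature (4, 21 degC) and 2 for RH (60%).
    Boundary knots default to the training-data range.
    """

    variable: str                      # "temp_c" or "rh_pct"
    knots: Tuple[float, ...]           # interior knots
    degree: int = 1
    boundary: Optional[Tuple[float, float]] = None

    @property
    def n_basis(self) -> int:
        return len(self.knots) + self.degree

    def with_boundary(self, x: np.ndarray) -> "BasisSpec":
        if self.boundary is not None:
            return self
        lo, hi = float(np.min(x)), float(np.max(x))
        if not all(lo < k < hi for k in self.knots):
            raise ValueError(
                f"interior knots {self.knots} outside data range ({lo}, {hi}) "
                f"for {self.variable}")
        return BasisSpec(self.variable, self.knots, self.degree, (lo, hi))

    def design(self, x: np.ndarray, drop_first: bool = True) -> np.ndarray:
        """Evaluate the basis at x; full basis sums to 1 on the support."""
        if self.boundary is None:
            raise ValueError("boundary knots unset; call with_boundary first")
        k = self.degree
        t = np.concatenate([[self.boundary[0]] * (k + 1), list(self.knots),
                            [self.boundary[1]] * (k + 1)])
        m = BSpline.design_matrix(np.asarray(x, dtype=float), t, k,
                                  extrapolate=True).toarray()
        return m[:, 1:] if drop_first else m


def default_bases() -> Dict[str, BasisSpec]:
    """Study bases: temperature knots 4 and 21 degC, RH knot 60%."""
    return {"temp_c": BasisSpec("temp_c", (4.0, 21.0)),
            "rh_pct": BasisSpec("rh_pct", (60.0,))}


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class CalibrationFit:
    """A fitted calibration model: named coefficients plus basis definitions."""

    gas: str                            # sensor type (CO, NO, NO2, OX)
    model_id: int
    coefficients: Dict[str, float]
    sensor_ids: List[str]               # training levels; first is reference
    bases: Dict[str, BasisSpec] = field(default_factory=dict)
    offsets: Dict[str, float] = field(default_factory=dict)  # models 6/7, ppb
    copollutant_term: bool = True   # False = co-pollutant column ablated
    train_n: int = 0
    train_start: Optional[pd.Timestamp] = None
    train_end: Optional[pd.Timestamp] = None
    resid_sd: float = float("nan")

    @property
    def target_gas(self) -> str:
        return TARGET_GAS[self.gas]

    def to_json(self) -> str:
        d = dict(gas=self.gas, model_id=self.model_id,
                 coefficients=self.coefficients, sensor_ids=self.sensor_ids,
                 offsets=self.offsets, train_n=self.train_n,
                 train_start=str(self.train_start), train_end=str(self.train_end),
                 resid_sd=self.resid_sd,
                 bases={v: dict(variable=b.variable, knots=list(b.knots),
                                degree=b.degree, boundary=list(b.boundary))
                        for v, b in self.bases.items()})
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "CalibrationFit":
        d = json.loads(s)
        bases = {v: BasisSpec(b["variable"], tuple(b["knots"]), b["degree"],
                              tuple(b["boundary"]))
                 for v, b in d.get("bases", {}).items()}
        return cls(gas=d["gas"], model_id=d["model_id"],
                   coefficients=d["coefficients"], sensor_ids=d["sensor_ids"],
                   bases=bases, offsets=d.get("offsets", {}),
                   train_n=d.get("train_n", 0), resid_sd=d.get("resid_sd", np.nan))


def _needs_copollutant(model_id: int, gas: str) -> bool:
    return model_id in (4, 5, 7) and COPOLLUTANT[gas] is not None


def build_design(records: pd.DataFrame,
                 model_id: int,
                 bases: Optional[Dict[str, BasisSpec]] = None,
                 copollutant: Optional[pd.DataFrame] = None,
                 sensor_ids: Optional[List[str]] = None,
                 offsets: Optional[Mapping[str, float]] = None,
                 specs: Optional[pd.DataFrame] = None,
                 copollutant_term: bool = True,
                 ) -> Tuple[pd.DataFrame, pd.Series, Dict[str, BasisSpec]]:
    """Build the named design table and response for one model of the ladder.

    ``records`` is a calibration table slice for a single sensor type, with
    columns period, monitor_id, sensor_id, we_mv, aux_mv, temp_c, rh_pct and
    (for fitting) ref_ppb. ``copollutant`` is a frame (monitor_id, period,
    copoll_ppb) of previously calibrated co-pollutant concentrations, required
    for models 4/5/7 on gases with an upstream dependency; rows missing it are
    dropped and counted, and more than 10% missing is an error. ``sensor_ids``
    fixes the contrast levels (training order) for prediction; ``offsets``
    (ppb, with ``specs`` for the mV conversion) pre-shift the WE for the
    common-intercept models 6/7.

    Returns (X, y, bases_used); y is NaN outside co-located rows.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"model_id must be in {MODEL_IDS}, got {model_id}")
    if model_id == 0:
        raise ValueError("Model 0 is closed-form; use manufacturer_predictions")
    gases = records["gas"].unique()
    if len(gases) != 1:
        raise ValueError(f"records must hold a single sensor type, got {gases}")
    gas = gases[0]

    df = records.copy()
    covars = ["we_mv", "aux_mv"]
    if model_id >= 2:
        covars += ["temp_c", "rh_pct"]
    n_missing = int(df[covars].isna().any(axis=1).sum())
    if n_missing:
        logger.info("build_design: dropping %d rows with missing covariates", n_missing)
        df = df.dropna(subset=covars)

    use_cop = copollutant_term and _needs_copollutant(model_id, gas)
    if use_cop:
        if copollutant is None:
            raise ChainOrderError(
                f"model {model_id} for {gas} requires calibrated "
                f"{COPOLLUTANT[gas]}; run the chain in order")
        cop = copollutant.rename(columns={copollutant.columns[-1]: "copoll_ppb"})
        df = df.merge(cop[["monitor_id", "period", "copoll_ppb"]],
                      on=["monitor_id", "period"], how="left")
        n_nocop = int(df["copoll_ppb"].isna().sum())
        if len(df) and n_nocop / len(df) > 0.10:
            raise ValueError(
                f"co-pollutant {COPOLLUTANT[gas]} missing for {n_nocop}/{len(df)} "
                "rows (>10%)")
        if n_nocop:
            logger.info("build_design: dropping %d rows lacking co-pollutant", n_nocop)
            df = df.dropna(subset=["copoll_ppb"])

    df = df.reset_index(drop=True)
    we = df["we_mv"].to_numpy(dtype=float)
    aux = df["aux_mv"].to_numpy(dtype=float)

    common_intercept = model_id in (6, 7)
    if common_intercept:
        if offsets is None or specs is None:
            raise ValueError("models 6/7 need an offset solution and sensor specs")
        sg = specs.set_index("sensor_id").eval("sensitivity * gain")
        shift_mv = df["sensor_id"].map(lambda s: offsets.get(s, 0.0)) \
            * df["sensor_id"].map(sg)
        we = we - shift_mv.to_numpy(dtype=float)

    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0

    if not common_intercept:
        if sensor_ids is None:
            sensor_ids = sorted(df["sensor_id"].unique())
        else:
            unseen = set(df["sensor_id"]) - set(sensor_ids)
            if unseen:
                raise ValueError(
                    f"unseen sensor_id(s) {sorted(unseen)} under model {model_id}; "
                    "sensor-specific intercepts are unavailable")
        for sid in sensor_ids[1:]:
            X[f"id_{sid}"] = (df["sensor_id"] == sid).astype(float)
    else:
        sensor_ids = sorted(df["sensor_id"].unique()) if sensor_ids is None else sensor_ids

    X["we"] = we
    X["aux"] = aux

    base_model = {6: 1, 7: 4}.get(model_id, model_id)
    bases_used: Dict[str, BasisSpec] = {}

    if base_model in (2, 3):
        X["temp"] = df["temp_c"].to_numpy(dtype=float)
        X["rh"] = df["rh_pct"].to_numpy(dtype=float)
        if base_model == 3:
            X["we_x_temp"] = X["we"] * X["temp"]
            X["we_x_rh"] = X["we"] * X["rh"]

    if base_model in (4, 5):
        if use_cop:
            X[f"{COPOLLUTANT[gas].lower()}_cal"] = df["copoll_ppb"].to_numpy(dtype=float)
        if bases is None:
            bases = default_bases()
        for var, short in (("temp_c", "temp"), ("rh_pct", "rh")):
            b = bases[var].with_boundary(df[var].to_numpy(dtype=float))
            bases_used[var] = b
            m = b.design(df[var].to_numpy(dtype=float))
            for j in range(m.shape[1]):
                X[f"{short}_spl{j + 1}"] = m[:, j]
                X[f"we_x_{short}_spl{j + 1}"] = X["we"] * m[:, j]
        if base_model == 5:
            for sid in sensor_ids[1:]:
                X[f"we_x_id_{sid}"] = X["we"] * (df["sensor_id"] == sid).astype(float)

    y = df["ref_ppb"] if "ref_ppb" in df.columns else pd.Series(np.nan, index=df.index)
    X.attrs["sensor_ids"] = list(sensor_ids)
    X.attrs["meta"] = df[["period", "monitor_id", "sensor_id"]]
    return X, y, bases_used


# ---------------------------------------------------------------------------
# fitting and prediction
# ---------------------------------------------------------------------------

def _collinear_columns(X: pd.DataFrame) -> List[str]:
    from scipy.linalg import qr

    a = X.to_numpy(dtype=float)
    _, r, piv = qr(a, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(a.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    bad += [X.columns[p] for p in piv[len(diag):]]
    return bad


def fit(X: pd.DataFrame, y: pd.Series,
        gas: str, model_id: int,
        bases: Optional[Dict[str, BasisSpec]] = None,
        offsets: Optional[Mapping[str, float]] = None,
        on_rank_deficient: str = "error",
        copollutant_term: bool = True) -> CalibrationFit:
    """Ordinary least squares on a named design table.

    Requires more rows than columns and a full-rank design; a rank-deficient
    design raises :class:`RankDeficientError` naming the collinear columns.
    ``on_rank_deficient="pinv"`` instead takes the minimum-norm solution,
    whose fitted values are still the unique least-squares projection — useful
    for exactly noise-free inputs, where a constant Aux electrode is perfectly
    collinear with the sensor intercepts.
    """
    mask = y.notna()
    Xf, yf = X.loc[mask], y.loc[mask]
    if len(Xf) <= Xf.shape[1]:
        raise ValueError(f"need more rows ({len(Xf)}) than columns ({Xf.shape[1]})")
    a = Xf.to_numpy(dtype=float)
    if np.linalg.matrix_rank(a) < a.shape[1]:
        if on_rank_deficient != "pinv":
            raise RankDeficientError(
                "rank-deficient design; collinear columns: "
                + ", ".join(_collinear_columns(Xf)))
        logger.warning("rank-deficient design; using minimum-norm solution")
    res = sm.OLS(yf.to_numpy(dtype=float), a).fit()
    coefs = dict(zip(Xf.columns, (float(b) for b in res.params)))
    meta = X.attrs.get("meta")
    periods = meta.loc[mask, "period"] if meta is not None else pd.Series(dtype="datetime64[ns]")
    return CalibrationFit(
        gas=gas, model_id=model_id, coefficients=coefs,
        sensor_ids=list(X.attrs.get("sensor_ids", [])),
        bases=bases or {}, offsets=dict(offsets or {}),
        copollutant_term=copollutant_term,
        train_n=int(len(Xf)),
        train_start=periods.min() if len(periods) else None,
        train_end=periods.max() if len(periods) else None,
        resid_sd=float(np.sqrt(res.mse_resid)))


def predict(fit_: CalibrationFit, records: pd.DataFrame,
            copollutant: Optional[pd.DataFrame] = None,
            specs: Optional[pd.DataFrame] = None,
            skip_unseen: bool = False) -> pd.DataFrame:
    """Apply a fitted model to averaged records; negative values are retained.

    Returns a frame (period, monitor_id, sensor_id, pred_ppb) covering the
    rows whose covariates are complete. Unseen sensor IDs are allowed only for
    the offset-based common-intercept models (6/7); with ``skip_unseen`` their
    rows are dropped with a warning instead of raising (used inside
    cross-validation, where a sensor's whole co-location can fall in the
    held-out weeks).
    """
    if skip_unseen and fit_.model_id in range(1, 6) and fit_.sensor_ids:
        known = records["sensor_id"].isin(fit_.sensor_ids)
        if not known.all():
            logger.warning("predict: skipping %d rows from sensors unseen in "
                           "training", int((~known).sum()))
            records = records[known]
    X, _, _ = build_design(records, fit_.model_id, bases=fit_.bases or None,
                           copollutant=copollutant,
                           sensor_ids=fit_.sensor_ids or None,
                           offsets=fit_.offsets if fit_.model_id in (6, 7) else None,
                           specs=specs,
                           copollutant_term=fit_.copollutant_term)
    missing = [c for c in fit_.coefficients if c not in X.columns]
    if missing:
        raise ValueError(f"records lack design columns {missing}")
    beta = np.array([fit_.coefficients[c] for c in fit_.coefficients])
    a = X[[c for c in fit_.coefficients]].to_numpy(dtype=float)
    out = X.attrs["meta"].copy()
    out["pred_ppb"] = a @ beta
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# calibration chain
# ---------------------------------------------------------------------------

@dataclass
class ChainResult:
    """Per-sensor-type fits and whole-deployment predictions."""

    fits: Dict[str, Optional[CalibrationFit]]
    predictions: Dict[str, pd.DataFrame]   # sensor type -> period/monitor/sensor/pred_ppb


def calibrate_chain(tables: Mapping[str, pd.DataFrame],
                    model_ids: Mapping[str, int],
                    specs: Optional[pd.DataFrame] = None,
                    bases: Optional[Dict[str, BasisSpec]] = None,
                    offsets: Optional[Mapping[str, Mapping[str, float]]] = None,
                    train_mask: Optional[Mapping[str, pd.Series]] = None,
                    copollutant_term: bool = True,
                    skip_unseen: bool = False,
                    ) -> ChainResult:
    """Fit the ladder in co-pollutant order and predict every deployment record.

    ``tables`` maps sensor type -> calibration table (all deployment records,
    co-located rows carrying ref_ppb). ``model_ids`` maps sensor type ->
    ladder model. Stages run CO -> NO -> NO2 -> OX so each co-pollutant term
    uses the calibrated series of the same monitor and period from the stage
    before. ``train_mask`` optionally restricts the rows used for fitting
    (cross-validation); predictions always cover all rows.
    """
    for st, mid in model_ids.items():
        dep = COPOLLUTANT[st]
        if copollutant_term and _needs_copollutant(mid, st) and dep not in model_ids:
            raise ChainOrderError(
                f"{st} model {mid} requires a calibrated {dep} stage in the chain")

    fits: Dict[str, Optional[CalibrationFit]] = {}
    preds: Dict[str, pd.DataFrame] = {}
    calibrated: Dict[str, pd.DataFrame] = {}

    for st in CHAIN_ORDER:
        if st not in model_ids:
            continue
        mid = model_ids[st]
        table = tables[st]
        cop = None
        if copollutant_term and _needs_copollutant(mid, st):
            dep = COPOLLUTANT[st]
            if dep not in calibrated:
                raise ChainOrderError(
                    f"{st} model {mid} needs calibrated {dep} first")
            cop = calibrated[dep].rename(columns={"pred_ppb": "copoll_ppb"})

        if mid == 0:
            if specs is None:
                raise ValueError("Model 0 requires manufacturer sensor specs")
            p = table[["period", "monitor_id", "sensor_id"]].copy()
            p["pred_ppb"] = manufacturer_predictions(table, specs).to_numpy()
            fits[st] = None
            preds[st] = p
        else:
            train = table[table["ref_ppb"].notna()] if "ref_ppb" in table.columns else table
            if train_mask is not None and st in train_mask:
                train = table[train_mask[st].reindex(table.index, fill_value=False)]
            offs = (offsets or {}).get(st)
            X, y, bases_used = build_design(
                train, mid, bases=bases, copollutant=cop,
                offsets=offs, specs=specs, copollutant_term=copollutant_term)
            f = fit(X, y, gas=st, model_id=mid, bases=bases_used, offsets=offs,
                    copollutant_term=copollutant_term)
            fits[st] = f
            preds[st] = predict(f, table, copollutant=cop, specs=specs,
                                skip_unseen=skip_unseen)
        calibrated[st] = preds[st]

    return ChainResult(fits=fits, predictions=preds)


# ---------------------------------------------------------------------------
# co-location baseline offsets
# ---------------------------------------------------------------------------

@dataclass
class OffsetSolution:
    """Per-sensor baseline offsets (ppb) from shared co-location periods.

    Offsets are relative: the anchor of each connected component is 0 and the
    solution is defined only within a component. ``anchor`` is the global
    anchor (longest-co-located sensor of the largest component).
    """

    offsets: Dict[str, float]
    anchor: str
    components: List[List[str]]
    edges: pd.DataFrame                # sensor_a, sensor_b, delta_ppb, n, se
    singletons: List[str] = field(default_factory=list)


def estimate_offsets(records: pd.DataFrame,
                     gas: str,
                     specs: pd.DataFrame,
                     min_overlap: int = 12) -> OffsetSolution:
    """Solve sensor baseline offsets from pairwise co-location differences.

    For every pair of same-type sensors sharing a site and averaging period,
    the edge value is the mean paired difference of the manufacturer-scale net
    signal ((WE - V0_WE) - (Aux - V0_Aux)) / (sensitivity * gain), assuming the
    baseline difference between sensors is constant in time. Offsets solve a
    weighted least-squares problem over the co-location graph, anchored at the
    longest-co-located sensor; disconnected components are solved separately
    (warning), and singleton sensors get offset 0 with a flag.
    """
    import networkx as nx

    sub = records[(records["gas"] == gas) & records["coloc"]].copy()
    if sub.empty:
        raise ValueError(f"no co-located records for sensor type {gas}")
    spec_map = specs.set_index("sensor_id")
    sg = (spec_map["sensitivity"] * spec_map["gain"])
    net0 = (spec_map["V0_WE"] - spec_map["V0_Aux"])
    sub["net_ppb"] = ((sub["we_mv"] - sub["aux_mv"])
                      - sub["sensor_id"].map(net0).to_numpy()) \
        / sub["sensor_id"].map(sg).to_numpy()

    counts = sub.groupby("sensor_id").size()
    sensors = sorted(counts.index)

    wide = sub.pivot_table(index=["site_id", "period"], columns="sensor_id",
                           values="net_ppb", aggfunc="mean")
    g = nx.Graph()
    g.add_nodes_from(sensors)
    edge_rows = []
    for i, a in enumerate(sensors):
        if a not in wide.columns:
            continue
        for b in sensors[i + 1:]:
            if b not in wide.columns:
                continue
            d = (wide[a] - wide[b]).dropna()
            if len(d) < min_overlap:
                continue
            se = float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.inf
            g.add_edge(a, b, delta=float(d.mean()), n=int(len(d)), se=se)
            edge_rows.append(dict(sensor_a=a, sensor_b=b, delta_ppb=float(d.mean()),
                                  n=int(len(d)), se=se))

    offsets: Dict[str, float] = {}
    components: List[List[str]] = []
    singletons: List[str] = []
    global_anchor: Optional[str] = None
    best_count = -1

    for comp in nx.connected_components(g):
        comp = sorted(comp)
        components.append(comp)
        anchor = max(comp, key=lambda s: (counts.get(s, 0), s))
        if counts.get(anchor, 0) > best_count:
            best_count, global_anchor = counts.get(anchor, 0), anchor
        if len(comp) == 1:
            offsets[comp[0]] = 0.0
            singletons.append(comp[0])
            continue
        idx = {s: j for j, s in enumerate(comp)}
        edges = [(u, v, d) for u, v, d in g.edges(comp, data=True)]
        rows, rhs, w = [], [], []
        for u, v, d in edges:
            r = np.zeros(len(comp))
            r[idx[u]], r[idx[v]] = 1.0, -1.0
            rows.append(r)
            rhs.append(d["delta"])
            w.append(np.sqrt(d["n"]))
        # anchor constraint with a dominant weight
        r = np.zeros(len(comp))
        r[idx[anchor]] = 1.0
        rows.append(r)
        rhs.append(0.0)
        w.append(1e6)
        A = np.asarray(rows) * np.asarray(w)[:, None]
        b = np.asarray(rhs) * np.asarray(w)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        sol = sol - sol[idx[anchor]]
        for s in comp:
            offsets[s] = float(sol[idx[s]])

    if len(components) > 1:
        logger.warning("offset graph for %s has %d disconnected components",
                       gas, len(components))
    edges_df = pd.DataFrame(edge_rows, columns=["sensor_a", "sensor_b",
                                                "delta_ppb", "n", "se"])
    return OffsetSolution(offsets=offsets, anchor=str(global_anchor),
                          components=components, edges=edges_df,
                          singletons=singletons)
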