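"""Calibration ladder: manufacturer conversion, design construction, OLS
fitting, the co-pollutant chain, and the co-location offset algorithm."""

import numpy as np
import pandas as pd
import pytest

import aircal as ac
from aircal.models import (BasisSpec, ChainOrderError, RankDeficientError,
                           build_design, default_bases)

from conftest import make_clean_world, build_tables

T0 = pd.Timestamp("2017-05-01T00:00:00Z")


# ---------------------------------------------------------------------------
# manufacturer conversion
# ---------------------------------------------------------------------------

def test_null_signal_is_zero_ppb():
    spec = dict(V0_WE=340.0, V0_Aux=335.0, sensitivity=0.4, gain=1.0)
    assert ac.manufacturer_concentration(340.0, 335.0, spec) == pytest.approx(0.0)


def test_net_signal_divided_by_sensitivity_gain():
    spec = dict(V0_WE=0.0, V0_Aux=0.0, sensitivity=0.4, gain=1.0)
    assert ac.manufacturer_concentration(100.0, 0.0, spec) == pytest.approx(250.0)
    # negative net signals yield negative concentrations, deliberately retained
    assert ac.manufacturer_concentration(-10.0, 0.0, spec) == pytest.approx(-25.0)


def test_zero_sensitivity_gain_errors():
    spec = dict(V0_WE=0.0, V0_Aux=0.0, sensitivity=0.0, gain=1.0)
    with pytest.raises(ValueError):
        ac.manufacturer_concentration(1.0, 0.0, spec)


# ---------------------------------------------------------------------------
# spline bases and design matrices
# ---------------------------------------------------------------------------

def test_basis_partition_of_unity():
    """With the intercept column retained the b-spline basis sums to one."""
    b = BasisSpec("temp_c", (4.0, 21.0), degree=1, boundary=(-5.0, 30.0))
    x = np.linspace(-5, 30, 200)
    full = b.design(x, drop_first=False)
    assert full.shape[1] == 4
    assert np.allclose(full.sum(axis=1), 1.0)
    assert b.design(x).shape[1] == b.n_basis == 3
    rh = BasisSpec("rh_pct", (60.0,), degree=1, boundary=(0.0, 100.0))
    assert rh.design(np.linspace(0, 100, 50)).shape[1] == rh.n_basis == 2


def test_knots_outside_data_range_rejected():
    b = BasisSpec("temp_c", (4.0, 21.0))
    with pytest.raises(ValueError, match="knots"):
        b.with_boundary(np.linspace(10.0, 18.0, 50))


def _records(n=40, sensors=("a", "b", "c"), gas="CO", seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for sid in sensors:
        rows.append(pd.DataFrame({
            "period": pd.date_range(T0, periods=n, freq="h"),
            "monitor_id": sid, "sensor_id": sid, "gas": gas,
            "we_mv": rng.normal(400, 30, n), "aux_mv": rng.normal(335, 5, n),
            "temp_c": rng.uniform(0, 26, n), "rh_pct": rng.uniform(45, 100, n),
            "ref_ppb": rng.normal(200, 40, n),
        }))
    return pd.concat(rows, ignore_index=True)


def test_model1_column_count_three_sensors():
    """Model 1 with 3 sensors: intercept + 2 contrasts + WE + Aux = 5 columns."""
    X, y, _ = build_design(_records(), 1)
    assert list(X.columns) == ["intercept", "id_b", "id_c", "we", "aux"]


def test_model4_o3_column_set_matches_final_model_structure():
    """O3 Model 4: intercept, contrasts, WE, Aux, calibrated NO2, 3 temperature
    bases, 2 RH bases, and 5 WE-interaction columns."""
    recs = _records(gas="OX")
    cop = recs[["monitor_id", "period"]].drop_duplicates().assign(copoll_ppb=10.0)
    X, y, bases = build_design(recs, 4, copollutant=cop)
    named = [c for c in X.columns if not c.startswith("id_")]
    assert named == ["intercept", "we", "aux", "no2_cal",
                     "temp_spl1", "we_x_temp_spl1",
                     "temp_spl2", "we_x_temp_spl2",
                     "temp_spl3", "we_x_temp_spl3",
                     "rh_spl1", "we_x_rh_spl1",
                     "rh_spl2", "we_x_rh_spl2"]
    assert len(named) == 14  # beta_0 ... beta_14 less the contrast vector
    assert bases["temp_c"].knots == (4.0, 21.0)
    assert bases["rh_pct"].knots == (60.0,)


def test_model_2_3_columns():
    X2, _, _ = build_design(_records(), 2)
    assert "temp" in X2.columns and "rh" in X2.columns
    assert "we_x_temp" not in X2.columns
    X3, _, _ = build_design(_records(), 3)
    assert {"we_x_temp", "we_x_rh"} <= set(X3.columns)


def test_missing_copollutant_over_ten_percent_errors():
    recs = _records(gas="OX")
    keep = recs[["monitor_id", "period"]].drop_duplicates().iloc[:50]
    cop = keep.assign(copoll_ppb=10.0)
    with pytest.raises(ValueError, match="10%"):
        build_design(recs, 4, copollutant=cop)


def test_model0_not_buildable():
    with pytest.raises(ValueError, match="closed-form"):
        build_design(_records(), 0)


# ---------------------------------------------------------------------------
# fitting and prediction
# ---------------------------------------------------------------------------

def test_exact_ols_recovery():
    """A response exactly linear in the design is recovered to machine
    precision."""
    X, _, _ = build_design(_records(seed=3), 1)
    beta = dict(intercept=5.0, id_b=-3.0, id_c=2.0, we=0.4, aux=-0.2)
    y = sum(beta[c] * X[c] for c in X.columns)
    f = ac.fit(X, pd.Series(y), "CO", 1)
    for c, b in beta.items():
        assert f.coefficients[c] == pytest.approx(b, abs=1e-9)
    assert f.resid_sd == pytest.approx(0.0, abs=1e-8)


def test_duplicated_column_raises_rank_error():
    X, y, _ = build_design(_records(), 1)
    X["id_b_dup"] = X["id_b"]
    y = pd.Series(np.random.default_rng(0).normal(size=len(X)))
    with pytest.raises(RankDeficientError, match="id_b"):
        ac.fit(X, y, "CO", 1)


def test_more_columns_than_rows_rejected():
    recs = _records(n=2, sensors=("a",))
    X, y, _ = build_design(recs, 1)
    with pytest.raises(ValueError, match="rows"):
        ac.fit(X, pd.Series(np.zeros(len(X))), "CO", 1)


def test_predict_on_training_rows_gives_fitted_values():
    recs = _records(seed=5)
    X, y, _ = build_design(recs, 1)
    f = ac.fit(X, y, "CO", 1)
    pred = ac.predict(f, recs)
    resid = pred["pred_ppb"].to_numpy() - y.to_numpy()
    assert abs(resid.mean()) < 1e-8  # intercept present -> residual mean 0


def test_unseen_sensor_rejected_for_intercept_models():
    f = ac.fit(*build_design(_records(), 1)[:2], gas="CO", model_id=1)
    new = _records(sensors=("zz",))
    with pytest.raises(ValueError, match="unseen"):
        ac.predict(f, new)


def test_negative_predictions_retained():
    recs = _records(seed=7)
    recs["ref_ppb"] = -50.0 + 0.0 * recs["ref_ppb"]
    X, y, _ = build_design(recs, 1)
    f = ac.fit(X, y, "CO", 1)
    pred = ac.predict(f, recs)
    assert (pred["pred_ppb"] < 0).all()


def test_fit_json_roundtrip():
    recs = _records(gas="OX")
    cop = recs[["monitor_id", "period"]].drop_duplicates().reset_index(drop=True)
    cop["copoll_ppb"] = np.random.default_rng(4).normal(12, 4, len(cop))
    X, y, bases = build_design(recs, 4, copollutant=cop)
    f = ac.fit(X, y, "OX", 4, bases=bases)
    f2 = ac.CalibrationFit.from_json(f.to_json())
    assert f2.coefficients == f.coefficients
    assert f2.bases["temp_c"].knots == (4.0, 21.0)
    assert f2.sensor_ids == f.sensor_ids


# ---------------------------------------------------------------------------
# calibration chain
# ---------------------------------------------------------------------------

def test_chain_order_violation_errors(coloc_tables):
    tables, specs = coloc_tables
    with pytest.raises(ChainOrderError):
        ac.calibrate_chain({"OX": tables["OX"]}, {"OX": 4}, specs=specs)


def test_co_stage_independent_of_chain_continuation(coloc_tables):
    """The CO fit is identical whether or not downstream stages run."""
    tables, specs = coloc_tables
    alone = ac.calibrate_chain({"CO": tables["CO"]}, {"CO": 3}, specs=specs)
    full = ac.calibrate_chain(tables, {"CO": 3, "NO": 4, "NO2": 4, "OX": 4},
                              specs=specs)
    assert alone.fits["CO"].coefficients == full.fits["CO"].coefficients
    pd.testing.assert_frame_equal(alone.predictions["CO"],
                                  full.predictions["CO"])


def test_chain_runs_all_four_gases(coloc_tables):
    tables, specs = coloc_tables
    chain = ac.calibrate_chain(tables, {"CO": 3, "NO": 4, "NO2": 4, "OX": 4},
                               specs=specs)
    assert set(chain.fits) == {"CO", "NO", "NO2", "OX"}
    for st, pred in chain.predictions.items():
        assert {"period", "monitor_id", "sensor_id", "pred_ppb"} <= set(pred.columns)
        assert pred["pred_ppb"].notna().all()


def test_model0_chain_requires_specs(coloc_tables):
    tables, _ = coloc_tables
    with pytest.raises(ValueError, match="specs"):
        ac.calibrate_chain({"CO": tables["CO"]}, {"CO": 0})


# ---------------------------------------------------------------------------
# offset algorithm
# ---------------------------------------------------------------------------

def _offset_world(baseline_ppb, overlap_days=((0, 14), (0, 21), (14, 21)),
                  seed=9):
    """Three same-gas sensors co-located per ``overlap_days``; declared V0_WE
    shifted by ``baseline_ppb`` so true baselines disagree with the spec
    sheet. Environmental coefficients are identical across sensors so paired
    differences isolate the baseline."""
    cfg = ac.SimConfig(n_monitors=3, duration_days=21, coloc_fraction=0.9,
                       seed=seed)
    truth = ac.simulate_truth(cfg)
    sensors = ac.make_sensors(cfg)
    for s in sensors:
        s.drift_slope = s.drift_aux_slope = 0.0
        s.temp_coef, s.temp_quad_coef, s.rh_coef = 0.35, 0.0, 0.08
    E = ac.EPOCH
    rows = []
    for (a, b), mid in zip(overlap_days, ("m00", "m01", "m02")):
        rows.append(dict(monitor_id=mid, location_id="site_0",
                         start=E + pd.Timedelta(days=a),
                         end=E + pd.Timedelta(days=b), is_colocation=True))
    sched = pd.DataFrame(rows)
    raw = ac.simulate_signals(truth, sensors, sched, seed=seed + 1,
                              noise_sd=cfg.noise_sd)
    clean = ac.apply_exclusions(raw, sched)
    ref = ac.aggregate_reference(ac.make_reference(truth, cfg), "hourly")
    table = ac.match_reference(ac.aggregate(clean[clean["gas"] == "CO"],
                                            "hourly"), ref, sched)
    specs = ac.sensor_specs(sensors)
    for sid, shift in baseline_ppb.items():
        sg = specs.loc[specs.sensor_id == sid, ["sensitivity", "gain"]].prod(axis=1)
        specs.loc[specs.sensor_id == sid, "V0_WE"] += shift * float(sg.iloc[0])
    return table, specs


def test_pairwise_offset_recovered():
    """A constant injected baseline difference between two overlapping sensors
    is recovered within 2 SE of the paired differences."""
    table, specs = _offset_world({"m00-CO": -8.0})  # m00 reads 8 ppb high
    sol = ac.estimate_offsets(table, "CO", specs)
    se = float(sol.edges["se"].max())
    others = [s for s in sol.offsets if s != "m00-CO"]
    rel = sol.offsets["m00-CO"] - sol.offsets[others[0]]
    assert rel == pytest.approx(8.0, abs=max(2 * se * 2, 0.3))


def test_transitive_chain_offsets():
    """With A-B and B-C overlaps only, offset(C) - offset(A) equals the sum of
    the injected pairwise baselines (propagated through B)."""
    table, specs = _offset_world({"m00-CO": -6.0, "m02-CO": 5.0},
                                 overlap_days=((0, 10), (0, 21), (11, 21)))
    sol = ac.estimate_offsets(table, "CO", specs)
    # A and C never overlap directly
    pairs = set(map(tuple, sol.edges[["sensor_a", "sensor_b"]].values))
    assert ("m00-CO", "m02-CO") not in pairs
    rel = sol.offsets["m00-CO"] - sol.offsets["m02-CO"]
    assert rel == pytest.approx(6.0 + 5.0, abs=0.5)


def test_singleton_sensor_flagged_zero():
    # m00 alone early; m01 and m02 overlap later, so m00 has no shared period
    table, specs = _offset_world({}, overlap_days=((0, 10), (11, 21), (11, 21)))
    sol = ac.estimate_offsets(table, "CO", specs)
    assert sol.offsets["m00-CO"] == 0.0
    assert "m00-CO" in sol.singletons
    assert any("m00-CO" in c and len(c) == 1 for c in sol.components)


def test_offset_anchor_invariance():
    """Re-anchoring shifts all offsets by one constant."""
    table, specs = _offset_world({"m00-CO": -6.0, "m02-CO": 5.0})
    sol = ac.estimate_offsets(table, "CO", specs)
    diffs = {s: sol.offsets[s] for s in sol.offsets}
    # shift-invariance: pairwise differences are well defined regardless of anchor
    base = diffs[sol.anchor]
    assert base == pytest.approx(0.0, abs=1e-9)
    vals = np.array(list(diffs.values()))
    assert np.ptp(vals) > 0  # non-trivial solution
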