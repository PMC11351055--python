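"""Critical-burden calibration, LC50 prediction, validation metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpmtox import (
    AbrahamDescriptors,
    BurdenEstimate,
    ChemicalRecord,
    ChemicalSet,
    burden_distribution,
    build_partition_table,
    chemical_critical_burden,
    estimate_burden,
    estimates_to_frame,
    evaluate_predictions,
    fit_table1,
    neg_log_to_mmol_per_kg,
    predict_lc50,
)
from tpmtox.errors import CalibrationError, DataError

from conftest import group_arrays


def make_set(logk, log_lc50, moa="baseline"):
    """A set whose descriptors are irrelevant; logK is supplied directly."""
    recs = tuple(
        ChemicalRecord(
            id=f"c{i}",
            descriptors=AbrahamDescriptors(E=0, S=0, A=0, B=0, V=1),
            log_lc50=y,
            moa=moa,
        )
        for i, y in enumerate(log_lc50)
    )
    return ChemicalSet("direct", recs), np.asarray(logk, dtype=float)


def brute_force_ols(x, y, center=(0.0, 0.0), half_width=10.0, rounds=14):
    """Independent least-squares oracle: iteratively refined grid search."""
    b0, b1 = center
    w = half_width
    for _ in range(rounds):
        g0 = np.linspace(b0 - w, b0 + w, 41)
        g1 = np.linspace(b1 - w, b1 + w, 41)
        sse = (
            (y[None, None, :] - g0[:, None, None] - g1[None, :, None] * x[None, None, :]) ** 2
        ).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        b0, b1 = g0[i], g1[j]
        w /= 5.0
    return b0, b1


def test_chemical_burden_trivial_values():
    assert chemical_critical_burden(4.0, -5.0) == -1.0  # 100 mmol/kg
    assert chemical_critical_burden(0.0, -2.5) == -2.5
    assert neg_log_to_mmol_per_kg(1.0) == pytest.approx(100.0)


def test_fixed_method_pins_burden_at_100mmol(tiny_set):
    est = estimate_burden(tiny_set, [1.0, 2.0, 3.0], "fixed_100mmol", phase="PA")
    assert est.neg_log_burden == 1.0
    assert est.slope_m == 1.0
    assert est.critical_burden_mmol_per_kg == pytest.approx(100.0)


def test_median_method_on_constant_burden():
    cset, logk = make_set([0.0, 1.0, 2.0], [-1.4, -2.4, -3.4])
    est = estimate_burden(cset, logk, "median")
    assert est.neg_log_burden == pytest.approx(1.4, abs=1e-12)
    assert est.slope_m == 1.0


def test_intercept_method_exact_fit():
    logk = np.array([0.0, 1.0, 2.0, 3.0])
    cset, _ = make_set(logk, list(-(1.4 + 0.95 * logk)))
    est = estimate_burden(cset, logk, "intercept")
    assert est.neg_log_burden == pytest.approx(1.4, abs=1e-10)
    assert est.slope_m == pytest.approx(0.95, abs=1e-10)
    assert est.rmse_fit == pytest.approx(0.0, abs=1e-10)
    assert est.r2_fit == pytest.approx(1.0, abs=1e-10)


def test_intercept_needs_three_points():
    cset, logk = make_set([0.0, 1.0], [-1.0, -2.0])
    with pytest.raises(CalibrationError, match="n >= 3"):
        estimate_burden(cset, logk, "intercept")


def test_missing_lc50_is_data_error(tiny_set):
    with pytest.raises(DataError, match="chem3"):
        estimate_burden(tiny_set, [1.0, 2.0, 3.0], "median")


def test_nonfinite_logk_aborts_unless_drop_requested():
    cset, logk = make_set([0.0, np.nan, 2.0, 3.0], [-1.0, -2.0, -3.0, -4.0])
    with pytest.raises(DataError, match="c1"):
        estimate_burden(cset, logk, "median")
    est = estimate_burden(cset, logk, "median", drop_nonfinite=True)
    assert est.n == 3


def test_ols_agrees_with_brute_force_grid_search(noisy_draw):
    _, cset, truth = noisy_draw
    sub, logk = group_arrays(cset, truth, "baseline")
    sub20 = ChemicalSet("head", sub.records[:20])
    x = logk[:20]
    est = estimate_burden(sub20, x, "intercept")
    y = -np.array([r.log_lc50 for r in sub20])
    b0, b1 = brute_force_ols(x, y)
    assert est.neg_log_burden == pytest.approx(b0, abs=1e-6)
    assert est.slope_m == pytest.approx(b1, abs=1e-6)


def test_ols_invariant_to_record_order(noisy_draw):
    _, cset, truth = noisy_draw
    sub, logk = group_arrays(cset, truth, "baseline")
    est = estimate_burden(sub, logk, "intercept", phase="p")
    perm = np.random.default_rng(1).permutation(len(sub))
    shuffled = ChemicalSet("perm", tuple(sub.records[i] for i in perm))
    est2 = estimate_burden(shuffled, logk[perm], "intercept", phase="p")
    assert est2.neg_log_burden == pytest.approx(est.neg_log_burden, abs=1e-10)
    assert est2.slope_m == pytest.approx(est.slope_m, abs=1e-10)
    assert est2.rmse_fit == pytest.approx(est.rmse_fit, abs=1e-10)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.permutations(list(range(6))))
def test_median_method_invariant_to_order(perm):
    logk = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
    lc50 = [-1.6, -2.2, -2.6, -3.4, -3.5, -4.4]
    cset, _ = make_set(logk, lc50)
    base = estimate_burden(cset, logk, "median").neg_log_burden
    cset_p = ChemicalSet("perm", tuple(cset.records[i] for i in perm))
    est = estimate_burden(cset_p, logk[perm], "median")
    assert est.neg_log_burden == base


def test_fit_table1_layout(noiseless_draw, polymer_system, air_water_system):
    _, cset, _ = noiseless_draw
    sets = {
        "baseline": cset.subset("baseline"),
        "less_inert": cset.subset("less_inert"),
    }
    table = build_partition_table(cset, [polymer_system, air_water_system])
    estimates = fit_table1(sets, table)
    assert len(estimates) == 4  # 2 groups x 2 phases
    frame = estimates_to_frame(estimates)
    assert set(frame["phase"]) == {"polymer_A", "air"}
    assert list(frame.columns) == [
        "group", "phase", "method", "neg_log_c_crit", "se_intercept",
        "slope_m", "se_slope", "rmse", "r2", "n",
    ]
    assert (frame["n"] == [20, 20, 12, 12]).all()


def test_predict_unity_mode():
    est = BurdenEstimate(phase="PA", group="baseline", method="fixed_100mmol",
                         neg_log_burden=1.0, n=10)
    assert predict_lc50(est, 3.0) == pytest.approx(-4.0)


def test_predict_fitted_mode_reported_pdms_coefficients():
    # intercept 1.933, slope 0.780 at logK 2 -> -(1.933 + 1.560) = -3.493
    est = BurdenEstimate(phase="PDMS", group="baseline", method="intercept",
                         neg_log_burden=1.933, slope_m=0.780, n=115)
    assert predict_lc50(est, 2.0, "fitted") == pytest.approx(-3.493, abs=1e-12)


def test_fitted_mode_requires_intercept_estimate():
    est = BurdenEstimate(phase="PA", group="baseline", method="median",
                         neg_log_burden=1.2, n=10)
    with pytest.raises(CalibrationError, match="fitted"):
        predict_lc50(est, 2.0, "fitted")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    logk=st.floats(-2, 8, allow_nan=False),
    burden=st.floats(-3, 5, allow_nan=False),
)
def test_unity_prediction_round_trips_to_burden(logk, burden):
    est = BurdenEstimate(phase="p", group="baseline", method="median",
                         neg_log_burden=burden, n=5)
    recovered = chemical_critical_burden(logk, predict_lc50(est, logk, "unity"))
    assert recovered == pytest.approx(-burden, abs=1e-9)


def test_evaluate_predictions_perfect_and_boundary_cases():
    perfect = evaluate_predictions([-3.0, -4.0], [-3.0, -4.0])
    assert perfect.rmse == 0.0
    assert all(v == 1.0 for v in perfect.within_factor.values())

    # residuals of exactly +-0.301 stay inside the inclusive factor-2 band
    rep = evaluate_predictions([-3.0, -4.0], [-3.301, -3.699])
    assert rep.within_factor[2] == 1.0

    single = evaluate_predictions([0.0], [1.0])
    assert single.rmse == pytest.approx(1.0)
    assert single.bias == pytest.approx(1.0)


def test_within_factor_fractions_nonincreasing(noisy_draw):
    _, cset, truth = noisy_draw
    sub, logk = group_arrays(cset, truth, "baseline")
    est = estimate_burden(sub, logk, "median")
    pred = predict_lc50(est, logk, "unity")
    rep = evaluate_predictions(pred, [r.log_lc50 for r in sub], ids=sub.ids)
    assert rep.within_factor[2] <= rep.within_factor[3] <= rep.within_factor[5]
    assert 0.0 <= rep.within_factor[2] and rep.within_factor[5] <= 1.0
    assert rep.rmse >= 0


def test_evaluate_predictions_length_mismatch():
    with pytest.raises(DataError):
        evaluate_predictions([1.0, 2.0], [1.0])


def test_burden_distribution_summary():
    cset, logk = make_set([0.0, 0.0, 0.0], [-1.2, -1.0, -0.9])
    dist = burden_distribution(cset, logk)
    assert dist["median"] == pytest.approx(-1.0)
    assert dist["min"] == -1.2 and dist["max"] == -0.9

    const, logk2 = make_set([1.0, 1.0], [-2.0, -2.0])
    d2 = burden_distribution(const, logk2)
    assert d2["min"] == d2["max"] == d2["mean"] == d2["median"] == -1.0
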