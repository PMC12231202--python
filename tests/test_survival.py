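from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from goosurv import survival, synthetic


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_exact_rational(durations, events):
    """Hand product-limit with exact rational arithmetic."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    out = {}
    s = Fraction(1)
    for t in sorted(set(durations[events == 1])):
        n = int((durations >= t).sum())
        d = int(((durations == t) & (events == 1)).sum())
        s *= Fraction(n - d, n)
        out[t] = s
    return out


def test_km_matches_exact_rational_product_limit():
    rng = np.random.default_rng(0)
    t = rng.integers(1, 15, 60).astype(float)          # heavy ties
    e = rng.integers(0, 2, 60)
    curve = survival.km_fit(t, e)
    exact = km_exact_rational(t, e)
    assert list(curve.times) == sorted(exact)
    for ti, si in zip(curve.times, curve.survival):
        assert si == pytest.approx(float(exact[ti]), abs=1e-14)


def test_km_single_event_fifth():
    # 5 subjects, one dies at t=5, the rest censored later: S(5) = 4/5
    curve = survival.km_fit([5, 8, 9, 10, 11], [1, 0, 0, 0, 0])
    assert curve.survival_at(5) == pytest.approx(0.8)
    assert curve.survival_at(4.99) == 1.0
    assert curve.median is None
    assert curve.n == 5 and curve.n_events == 1


def test_km_median_and_groups():
    curve = survival.km_fit([1, 2, 3, 4], [1, 1, 1, 1])
    assert curve.median == 2.0      # S first reaches 0.5 at the second event
    by = survival.km_fit([1, 2, 3, 4], [1, 1, 0, 0], groups=["a", "a", "b", "b"])
    assert set(by) == {"a", "b"}
    assert by["b"].n_events == 0 and by["b"].median is None


def test_km_validation():
    with pytest.raises(ValueError):
        survival.km_fit([], [])
    with pytest.raises(ValueError):
        survival.km_fit([0.0, 1.0], [1, 1])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_hand_example():
    # Two groups of three; classic hand computation.
    t = [6, 7, 10, 15, 19, 25]
    e = [1, 0, 1, 1, 0, 1]
    g = ["A", "A", "A", "B", "B", "B"]
    O = {"A": 0.0, "B": 0.0}
    E = {"A": 0.0, "B": 0.0}
    V = 0.0
    ta, ea, ga = np.array(t, float), np.array(e), np.array(g)
    for u in sorted(set(ta[ea == 1])):
        at = ta >= u
        n = at.sum()
        d = ((ta == u) & (ea == 1)).sum()
        for lbl in ("A", "B"):
            ng = (at & (ga == lbl)).sum()
            O[lbl] += ((ta == u) & (ea == 1) & (ga == lbl)).sum()
            E[lbl] += d * ng / n
        nA = (at & (ga == "A")).sum()
        if n > 1:
            V += d * (n - d) * nA * (n - nA) / (n**2 * (n - 1))
    expect = (O["A"] - E["A"]) ** 2 / V
    chi2, df, p = survival.logrank_test(t, e, g)
    assert df == 1
    assert chi2 == pytest.approx(expect, rel=1e-12)
    assert p == pytest.approx(float(stats.chi2.sf(expect, 1)), rel=1e-12)


def test_logrank_matches_lifelines():
    lifelines = pytest.importorskip("lifelines")
    from lifelines.statistics import multivariate_logrank_test

    rng = np.random.default_rng(1)
    t = rng.exponential(100, 30).round(1) + 1
    e = rng.integers(0, 2, 30)
    g = rng.choice(["x", "y", "z"], 30)
    e[0] = 1  # ensure at least one event
    chi2, df, p = survival.logrank_test(t, e, g)
    ref = multivariate_logrank_test(t, g, e)
    assert df == 2
    assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
    assert p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_validation():
    with pytest.raises(ValueError):
        survival.logrank_test([1, 2], [1, 1], ["a", "a"])
    with pytest.raises(ValueError):
        survival.logrank_test([1, 2], [0, 0], ["a", "b"])


# ---------------------------------------------------------------------------
# Cox model
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def surv_df():
    return synthetic.simulate_survival_data(150, seed=7)


def test_cox_matches_lifelines(surv_df):
    lifelines = pytest.importorskip("lifelines")
    cph = lifelines.CoxPHFitter()
    cph.fit(surv_df, duration_col="survival_days", event_col="event",
            fit_options={"precision": 1e-9})
    fit = survival.cox_fit(surv_df, ["actavg_z", "wdsp_z"])
    np.testing.assert_allclose(fit.beta_raw, cph.params_.to_numpy(), atol=1e-6)
    np.testing.assert_allclose(fit.se_raw, cph.standard_errors_.to_numpy(), atol=1e-6)
    assert fit.log_partial_lik == pytest.approx(cph.log_likelihood_, abs=1e-8)
    assert fit.aic == pytest.approx(cph.AIC_partial_, abs=1e-6)
    assert fit.concordance == pytest.approx(cph.concordance_index_, abs=1e-9)


def test_cox_ties_match_lifelines():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {
            "survival_days": rng.integers(1, 12, 80).astype(float),  # many ties
            "event": rng.integers(0, 2, 80),
            "x": rng.normal(0, 1, 80),
        }
    )
    cph = lifelines.CoxPHFitter()
    cph.fit(df, duration_col="survival_days", event_col="event",
            fit_options={"precision": 1e-9})
    fit = survival.cox_fit(df, ["x"])
    assert fit.beta_raw[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
    assert fit.se_raw[0] == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-6)


def test_cox_scale_invariance(surv_df):
    fit = survival.cox_fit(surv_df, ["actavg_z", "wdsp_z"])
    scaled = surv_df.assign(actavg_z=surv_df["actavg_z"] * 10.0)
    fit2 = survival.cox_fit(scaled, ["actavg_z", "wdsp_z"])
    np.testing.assert_allclose(fit2.beta, fit.beta, atol=1e-8)        # per-sd scale
    assert fit2.beta_raw[0] == pytest.approx(fit.beta_raw[0] / 10.0, abs=1e-9)
    assert fit2.log_partial_lik == pytest.approx(fit.log_partial_lik, abs=1e-8)


def test_cox_null_model(surv_df):
    fit = survival.cox_fit(surv_df, [])
    assert fit.aic == pytest.approx(-2.0 * fit.log_partial_lik_null)
    assert fit.global_score_chi2 == 0.0
    assert fit.covariates == []


def test_cox_null_covariate_is_insignificant():
    rng = np.random.default_rng(11)
    df = synthetic.simulate_survival_data(300, log_hrs=(0.0, 0.0), seed=12)
    fit = survival.cox_fit(df, ["actavg_z", "wdsp_z"])
    # with no true effect, |beta| should be within ~3 SEs of zero
    assert (np.abs(fit.beta) < 3.5 * fit.se).all()


def test_cox_recovers_known_coefficient():
    df = synthetic.simulate_survival_data(800, log_hrs=(np.log(2.0), 0.0),
                                          baseline_per_day=0.004, seed=13)
    fit = survival.cox_fit(df, ["actavg_z"])
    assert fit.beta_raw[0] == pytest.approx(np.log(2.0), abs=0.15)
    assert fit.hr_ci_low[0] < 2.0 < fit.hr_ci_high[0]
    assert fit.p[0] < 1e-6


def test_cox_constant_covariate_rejected(surv_df):
    with pytest.raises(ValueError, match="constant"):
        survival.cox_fit(surv_df.assign(c=1.0), ["c"])


def test_cox_missing_values_rejected(surv_df):
    bad = surv_df.copy()
    bad.loc[0, "actavg_z"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        survival.cox_fit(bad, ["actavg_z"])


def test_cox_separation_flagged_or_raises():
    # a covariate perfectly ordering events from non-events cannot converge
    df = pd.DataFrame(
        {
            "survival_days": np.r_[np.arange(1.0, 11.0), np.arange(20.0, 30.0)],
            "event": np.r_[np.ones(10, int), np.zeros(10, int)],
            "x": np.r_[np.ones(10), np.zeros(10)],
        }
    )
    try:
        fit = survival.cox_fit(df, ["x"])
        assert fit.flags.get("possible_separation") == ["x"]
    except survival.ConvergenceError as err:
        assert err.trace


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_concordance_extremes():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1, 1, 1, 1])
    perfect_risk = np.array([4.0, 3.0, 2.0, 1.0])   # earlier death = higher risk
    assert survival._concordance(t, e, perfect_risk) == 1.0
    assert survival._concordance(t, e, -perfect_risk) == 0.0
    assert survival._concordance(t, e, np.zeros(4)) == 0.5


# ---------------------------------------------------------------------------
# Schoenfeld PH test
# ---------------------------------------------------------------------------

def test_schoenfeld_calibrated_under_ph():
    rejections = 0
    trials = 40
    for s in range(trials):
        df = synthetic.simulate_survival_data(120, log_hrs=(np.log(0.6), np.log(1.6)),
                                              baseline_per_day=0.004, seed=1000 + s)
        fit = survival.cox_fit(df, ["actavg_z", "wdsp_z"])
        p = survival.schoenfeld_test(fit, df)
        rejections += int(min(p.values()) < 0.05)
    # two tests per trial at alpha=.05 under H0: expect <= ~10% joint rejections
    assert rejections / trials < 0.25


def test_schoenfeld_detects_time_varying_effect():
    rng = np.random.default_rng(21)
    n = 400
    x = rng.normal(0, 1, n)
    # effect reverses over time: early hazard up with x, late hazard down
    t1 = rng.exponential(1.0 / (0.02 * np.exp(1.5 * x)))
    t = np.where(t1 < 30.0, t1, 30.0 + rng.exponential(1.0 / (0.02 * np.exp(-1.5 * x))))
    df = pd.DataFrame({"survival_days": np.minimum(t, 200.0), "event": (t <= 200.0).astype(int), "x": x})
    fit = survival.cox_fit(df, ["x"])
    p = survival.schoenfeld_test(fit, df)
    assert p["x"] < 0.01


def test_schoenfeld_needs_events(surv_df):
    fit = survival.cox_fit(surv_df.iloc[:40], ["actavg_z"])
    few = surv_df.iloc[:40].copy()
    few["event"] = 0
    few.loc[few.index[0], "event"] = 1
    fit2 = survival.cox_fit(few.assign(actavg_z=surv_df["actavg_z"].iloc[:40] + 0.0), [])
    assert survival.schoenfeld_test(fit2, few) == {}


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def vif_by_direct_regression(X, j):
    """1 / (1 - R^2) from an explicit least-squares auxiliary regression."""
    y = X[:, j]
    A = np.column_stack([np.ones(len(y)), np.delete(X, j, axis=1)])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    r2 = 1.0 - ((y - A @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    return 1.0 / (1.0 - r2)


def test_vif_matches_statsmodels_and_direct():
    rng = np.random.default_rng(30)
    n = 200
    a = rng.normal(0, 1, n)
    b = 0.8 * a + rng.normal(0, 0.6, n)
    c = rng.normal(0, 1, n)
    df = pd.DataFrame({"a": a, "b": b, "c": c})
    X = df.to_numpy()
    for j in range(3):
        ours = survival._vif_one(X, j)
        assert ours == pytest.approx(vif_by_direct_regression(X, j), rel=1e-10)
    statsmodels = pytest.importorskip("statsmodels.stats.outliers_influence")
    Xc = np.column_stack([np.ones(n), X])
    for j in range(3):
        ref = statsmodels.variance_inflation_factor(Xc, j + 1)
        assert survival._vif_one(X, j) == pytest.approx(ref, rel=1e-8)


def test_vif_screen_drops_collinear():
    rng = np.random.default_rng(31)
    n = 150
    a = rng.normal(0, 1, n)
    dup = a + rng.normal(0, 0.01, n)      # near-duplicate of a
    c = rng.normal(0, 1, n)
    df = pd.DataFrame({"c": c, "a": a, "dup": dup})
    retained, dropped = survival.vif_screen(df, ["c", "a", "dup"], threshold=5.0)
    assert len(dropped) == 1
    assert dropped[0][0] == "a"           # alphabetical tie-break on the pair
    assert retained == ["c", "dup"]       # caller order preserved
    r2, d2 = survival.vif_screen(df[["c", "a"]], ["c", "a"])
    assert r2 == ["c", "a"] and d2 == []


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def test_model_select_enumerates_all_subsets(surv_df):
    sel = survival.model_select(surv_df, ["actavg_z", "wdsp_z"])
    assert len(sel.table) == 4                      # {}, {a}, {w}, {a,w}
    assert sel.table["delta_aic"].iloc[0] == 0.0
    assert all(aic >= sel.table["aic"].iloc[0] for aic in sel.table["aic"])


def test_model_select_finds_signal_among_noise():
    rng = np.random.default_rng(40)
    df = synthetic.simulate_survival_data(500, log_hrs=(np.log(0.4), np.log(2.5)),
                                          baseline_per_day=0.004, seed=41)
    df["noise1"] = rng.normal(0, 1, len(df))
    df["noise2"] = rng.normal(0, 1, len(df))
    sel = survival.model_select(df, ["actavg_z", "wdsp_z", "noise1", "noise2"])
    assert {"actavg_z", "wdsp_z"} <= set(sel.final_covariates)
    assert not {"noise1", "noise2"} & set(sel.final_covariates)
    added = {step["added"] for step in sel.stepwise_path}
    assert {"actavg_z", "wdsp_z"} <= added


def test_model_select_all_noise_prefers_null():
    rng = np.random.default_rng(42)
    df = synthetic.simulate_survival_data(400, log_hrs=(0.0, 0.0), seed=44)
    sel = survival.model_select(df, ["actavg_z", "wdsp_z"])
    assert sel.final_covariates == ()
    assert sel.final is None
    assert sel.null_aic == sel.table.loc[sel.table["k"] == 0, "aic"].iloc[0]


def test_model_select_candidate_limit(surv_df):
    with pytest.raises(ValueError, match="15"):
        survival.model_select(surv_df, [f"c{i}" for i in range(16)])
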