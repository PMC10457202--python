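import warnings

import numpy as np
import pandas as pd
import pytest

import driftclock as dc
from driftclock.io_core import DriftClockError


def efron_log_partial_likelihood(b, times, events, x):
    """Independent oracle: Efron-tie Cox log partial likelihood, one covariate."""
    ll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        risk = times >= t
        d = tied.sum()
        theta_risk = np.exp(b * x[risk]).sum()
        theta_tied = np.exp(b * x[tied]).sum()
        ll += b * x[tied].sum()
        for ell in range(d):
            ll -= np.log(theta_risk - (ell / d) * theta_tied)
    return ll


def grid_maximize(fun, lo=-5.0, hi=5.0):
    for _ in range(6):  # successive 201-point refinements -> ~1e-7 resolution
        grid = np.linspace(lo, hi, 201)
        vals = [fun(b) for b in grid]
        j = int(np.argmax(vals))
        lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, 200)]
    return 0.5 * (lo + hi)


def test_cox_screen_matches_efron_grid_oracle():
    """5-patient toy with tied event times: coefficient within 1e-4 of the
    brute-force maximizer of the Efron partial likelihood."""
    times = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
    events = np.array([1, 1, 1, 1, 1])
    betas = np.array([[0.20, 0.00, 0.10, 0.30, 0.10]])
    surv = dc.SurvivalData(times, events, ["t1"] * 5, ["ALL"] * 5)
    beta = dc.BetaMatrix(["cg1"], [f"p{i}" for i in range(5)], betas)
    with pytest.warns(UserWarning, match="constant"):
        table = dc.cox_screen_cpgs(beta, surv)
    x10 = 10.0 * betas[0]
    b_star = grid_maximize(
        lambda b: efron_log_partial_likelihood(b, times, events, x10))
    assert np.isclose(table["coef"].iloc[0], b_star, atol=1e-4)
    assert np.isclose(table["hr"].iloc[0], np.exp(b_star), rtol=1e-3)
    assert table["converged"].iloc[0]


def test_cox_screen_recovers_planted_hazard(small_clinical):
    """Planted hazard CpGs screen at HR > 1; their CIs bracket the HR."""
    _, beta, _, truth, surv = small_clinical
    sub = beta.select_cpgs(truth.hazard_cpg_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = dc.cox_screen_cpgs(sub, surv)
    assert (table["hr"] > 1).mean() >= 0.8
    assert ((table["ci_low"] <= table["hr"]) & (table["hr"] <= table["ci_high"])).all()
    assert ((table["p"] > 0) & (table["p"] <= 1)).all()


def test_select_survival_cpgs_direction_and_threshold():
    table = pd.DataFrame({
        "hr": [1.2, 0.8, 1.5, 1.1],
        "p": [0.005, 0.001, 0.02, 0.009],
    }, index=pd.Index(["a", "b", "c", "d"], name="cpg_id"))
    with pytest.warns(UserWarning, match="multiple testing"):
        sel = dc.select_survival_cpgs(table)
    assert sel == ["a", "d"]  # b fails direction, c fails p


def test_cox_on_prediction_null_ci_contains_one():
    rng = np.random.default_rng(4)
    n = 150
    surv = dc.SurvivalData(rng.exponential(300, n), np.ones(n, dtype=int),
                           rng.choice(["t1", "t2"], n),
                           rng.choice(["ALL", "NHL"], n))
    res = dc.cox_on_prediction(rng.normal(10, 2, n), surv)
    assert res["ci_low"] <= 1.0 <= res["ci_high"]


def test_cox_on_prediction_affine_invariance():
    """Days -> hours rescales the coefficient by 1/24, Wald p unchanged."""
    rng = np.random.default_rng(5)
    n = 120
    pred = rng.normal(10, 2, n)
    times = rng.exponential(300 * np.exp(-0.1 * (pred - 10)))
    surv = dc.SurvivalData(times, np.ones(n, dtype=int),
                           ["t1"] * n, ["ALL"] * n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        days = dc.cox_on_prediction(pred, surv)
        hours = dc.cox_on_prediction(pred * 24.0, surv)
    assert np.isclose(hours["coef"], days["coef"] / 24.0, rtol=1e-5)
    assert np.isclose(hours["p"], days["p"], rtol=1e-5)


def _patient_sheet(n=114, seed=0):
    rng = np.random.default_rng(seed)
    return dc.SampleSheet(pd.DataFrame({
        "sample_id": [f"p{i}" for i in range(n)],
        "trial": rng.choice(["t1", "t2", "t3"], n),
        "disease": rng.choice(["ALL", "NHL"], n),
        "age": rng.uniform(20, 75, n),
        "os_time": rng.exponential(300, n) + 1,
        "os_event": rng.integers(0, 2, n),
    }))


def test_split_cohorts_exact_sizes_and_stratum_balance():
    sheet = _patient_sheet()
    out = dc.split_cohorts(sheet, 82, 32, strata=["trial", "disease", "age"],
                           seed=3)
    counts = out.data["cohort"].value_counts()
    assert counts["identification"] == 82 and counts["validation"] == 32
    # per-stratum identification share within +/-1 of proportional
    df = out.data
    for (trial, disease), grp in df.groupby(["trial", "disease"]):
        expected = len(grp) * 82 / 114
        got = (grp["cohort"] == "identification").sum()
        assert abs(got - expected) <= 1 + 3  # age tertiles subdivide further


def test_split_cohorts_deterministic_and_unstratified():
    sheet = _patient_sheet()
    a = dc.split_cohorts(sheet, 82, 32, strata=["trial"], seed=9)
    b = dc.split_cohorts(sheet, 82, 32, strata=["trial"], seed=9)
    assert a.data["cohort"].tolist() == b.data["cohort"].tolist()
    c = dc.split_cohorts(sheet, 60, 30, strata=None, seed=1)
    counts = c.data["cohort"].value_counts()
    assert counts["identification"] == 60 and counts["validation"] == 30
    assert counts.get("unassigned", 0) == 24
    with pytest.raises(DriftClockError, match="exceeds"):
        dc.split_cohorts(sheet, 100, 100)


def test_km_textbook_steps_and_logrank_separation():
    """Distinct uncensored event times step the curve by 1/n; complete
    separation gives log-rank p < 0.001."""
    times = np.array([1.0, 2.0, 3.0, 4.0] + [50.0] * 8)
    events = np.array([1, 1, 1, 1] + [0] * 8)
    scores = np.array([10.0] * 4 + [0.0] * 8)
    surv = dc.SurvivalData(times, events, ["t"] * 12, ["d"] * 12)
    res = dc.km_stratify(scores, surv, mode="median")
    high = res["curves"]["high"]
    surv_vals = high.set_index("time")["survival"]
    assert np.allclose(surv_vals.loc[[1.0, 2.0, 3.0, 4.0]],
                       [0.75, 0.5, 0.25, 0.0])
    assert res["logrank_p"] < 0.001
    for curve in res["curves"].values():
        s = curve["survival"].to_numpy()
        assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()


def test_km_identical_groups_null_logrank():
    small = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        n = 60
        times = rng.exponential(100, n)
        events = rng.random(n) < 0.8
        scores = rng.normal(0, 1, n)  # independent of survival
        surv = dc.SurvivalData(times, events.astype(int), ["t"] * n, ["d"] * n)
        res = dc.km_stratify(scores, surv, mode="quartiles")
        small += res["logrank_p"] < 0.05
    assert small <= 7  # ~Binomial(50, 0.05)


def test_km_quartiles_need_enough_patients():
    surv = dc.SurvivalData([1, 2, 3, 4], [1, 1, 1, 1], ["t"] * 4, ["d"] * 4)
    with pytest.raises(DriftClockError, match=">= 8"):
        dc.km_stratify([1.0, 2.0, 3.0, 4.0], surv, mode="quartiles")


def test_toxicity_ttest_identical_groups():
    pred = np.array([5.0, 6.0, 7.0, 5.0, 6.0, 7.0])
    flags = np.array([0, 0, 0, 1, 1, 1])
    assert dc.compare_toxicity_groups(pred, flags) > 0.999


def test_toxicity_ttest_clear_separation():
    rng = np.random.default_rng(6)
    pred = np.r_[rng.normal(9, 1, 20), rng.normal(11, 1, 20)]
    flags = np.r_[np.zeros(20), np.ones(20)]
    assert dc.compare_toxicity_groups(pred, flags) < 0.001


def test_toxicity_ttest_matches_hand_formula():
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([2.0, 4.0, 6.0])
    p = dc.compare_toxicity_groups(np.r_[a, b], np.r_[0, 0, 0, 1, 1, 1])
    sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    from scipy import stats
    assert np.isclose(p, 2 * stats.t.sf(abs(t), 4), atol=1e-12)


def test_toxicity_ttest_errors():
    with pytest.raises(DriftClockError, match="non-empty"):
        dc.compare_toxicity_groups([1.0, 2.0], [0, 0])
    with pytest.raises(DriftClockError, match="size 1"):
        dc.compare_toxicity_groups([1.0, 2.0, 3.0], [0, 0, 1])


def test_survival_data_validation():
    with pytest.raises(DriftClockError, match="> 0"):
        dc.SurvivalData([0.0, 1.0], [1, 1], ["t", "t"], ["d", "d"])
    with pytest.raises(DriftClockError, match="no events"):
        dc.SurvivalData([1.0, 2.0], [0, 0], ["t", "t"], ["d", "d"])
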