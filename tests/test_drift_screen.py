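import numpy as np
import pytest
from scipy import stats

import driftclock as dc
from driftclock.io_core import DriftClockError


def _beta(values, sample_prefix="s"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return dc.BetaMatrix(
        [f"cg{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
        values,
    )


DAYS = np.array([0.0, 8.0, 15.0, 22.0])


def test_linear_beta_gives_r_one():
    beta = _beta(0.2 + 0.01 * DAYS)
    r = dc.correlate_with_time(beta, DAYS)
    assert np.isclose(r.iloc[0], 1.0)


def test_constant_beta_gives_r_zero_by_convention():
    beta = _beta(np.full(4, 0.5))
    r = dc.correlate_with_time(beta, DAYS)
    assert r.iloc[0] == 0.0


def test_missing_values_pairwise_complete():
    vals = 0.2 + 0.01 * np.array([0.0, 8.0, 15.0, 22.0, 30.0])
    vals[4] = np.nan
    beta = _beta(vals)
    r = dc.correlate_with_time(beta, np.r_[DAYS, 30.0])
    assert np.isclose(r.iloc[0], 1.0)
    # fewer than 3 complete pairs: NaN with a warning
    with pytest.warns(UserWarning, match="complete pairs"):
        r2 = dc.correlate_with_time(_beta([[0.2, 0.3, np.nan, np.nan]]), DAYS)
    assert np.isnan(r2.iloc[0])


def test_all_days_identical_is_an_error():
    beta = _beta([[0.1, 0.2, 0.3]])
    with pytest.raises(DriftClockError, match="time gradient"):
        dc.correlate_with_time(beta, [5.0, 5.0, 5.0])


def test_null_betas_rarely_pass_threshold():
    """Random β, 1000 CpGs x 12 samples: |r| > 0.9 for < 1% of CpGs."""
    frac = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        beta = _beta(rng.uniform(0, 1, size=(1000, 12)))
        days = np.tile(DAYS, 3)
        r = dc.correlate_with_time(beta, days)
        frac.append((r.abs() > 0.9).mean())
    assert np.mean(frac) < 0.01


def test_selection_threshold_is_strict():
    import pandas as pd
    r = pd.Series([0.9, 0.91, -0.9, -0.95], index=list("abcd"))
    hyper, hypo = dc.select_drift_cpgs(r)
    assert hyper == ["b"] and hypo == ["d"]


def test_affine_rescaling_of_days_leaves_r():
    rng = np.random.default_rng(0)
    beta = _beta(np.clip(0.3 + 0.01 * DAYS + rng.normal(0, 0.01, 4), 0, 1))
    r1 = dc.correlate_with_time(beta, DAYS)
    r2 = dc.correlate_with_time(beta, 24.0 * DAYS + 7.0)
    assert np.allclose(r1, r2, atol=1e-12)


def test_age_exclusion_removes_planted_age_cpgs():
    """10 planted age CpGs among 300 candidates: all removed, <=1 false."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n_ref = 474  # blood age-reference cohort scale
        ages = rng.uniform(20, 70, n_ref)
        age_ids = [f"age{i}" for i in range(10)]
        drift_ids = [f"drift{i}" for i in range(290)]
        vals_age = np.clip(0.001 * ages[None, :] + 0.2
                           + rng.normal(0, 0.001, (10, n_ref)), 0, 1)
        vals_null = np.clip(rng.uniform(0.2, 0.8, (290, 1))
                            + rng.normal(0, 0.03, (290, n_ref)), 0, 1)
        ref = dc.BetaMatrix(age_ids + drift_ids,
                            [f"p{i}" for i in range(n_ref)],
                            np.vstack([vals_age, vals_null]))
        kept, removed = dc.exclude_age_cpgs(age_ids + drift_ids, ref, ages)
        assert set(age_ids) <= set(removed)
        assert len(set(removed) - set(age_ids)) <= 1


def test_age_exclusion_policies_and_errors():
    rng = np.random.default_rng(1)
    ages = rng.uniform(20, 70, 12)
    ref = dc.BetaMatrix(["cg_present"], [f"p{i}" for i in range(12)],
                        rng.uniform(0.4, 0.6, (1, 12)))
    with pytest.warns(UserWarning, match="absent"):
        kept, removed = dc.exclude_age_cpgs(["cg_present", "cg_absent"], ref, ages)
    assert "cg_absent" in kept
    with pytest.raises(DriftClockError, match="identical"):
        dc.exclude_age_cpgs(["cg_present"], ref, np.full(12, 40.0))
    with pytest.raises(DriftClockError, match=">= 10"):
        small = dc.BetaMatrix(["cg1"], ["p0", "p1"], [[0.4, 0.5]])
        dc.exclude_age_cpgs(["cg1"], small, [20.0, 30.0])


def test_differential_methylation_clear_effect():
    """Δ = 0.25 with sd 0.02 at n = 4+4 is detected as hyper; the t statistic
    is far beyond the t(6) significance bound."""
    rng = np.random.default_rng(2)
    a = np.clip(0.30 + rng.normal(0, 0.02, (40, 4)), 0, 1)
    b = np.clip(0.55 + rng.normal(0, 0.02, (40, 4)), 0, 1)
    hits = np.hstack([a[:5], b[:5]])
    nulls = np.hstack([a[5:], a[5:] + rng.normal(0, 0.02, (35, 4))])
    beta = _beta(np.vstack([hits, np.clip(nulls, 0, 1)]))
    table = dc.differential_methylation(
        beta, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
    assert table.iloc[:5]["significant"].all()
    assert (table.iloc[:5]["direction"] == "hyper").all()


def test_differential_methylation_group_size_error():
    beta = _beta(np.random.default_rng(0).uniform(0, 1, (5, 4)))
    with pytest.raises(DriftClockError, match=">= 2"):
        dc.differential_methylation(beta, ["s0"], ["s1", "s2"])


def test_differential_methylation_null_fdr():
    """Null data: the BH-significant fraction stays at or below alpha."""
    total_sig = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.3, 0.7, size=(200, 1))
        beta = _beta(np.clip(base + rng.normal(0, 0.05, (200, 8)), 0, 1))
        t = dc.differential_methylation(
            beta, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
            delta=0.0)
        total_sig += t["significant"].sum()
    assert total_sig / (50 * 200) <= 0.05


def test_full_screen_matches_bruteforce(small_culture):
    """Vectorised screen equals a CpG-by-CpG scipy.stats.pearsonr loop."""
    _, beta, sheet, _ = small_culture
    days = sheet.column("days_in_culture").to_numpy(float)
    sub = beta.select_cpgs(beta.cpg_ids[:200])
    r = dc.correlate_with_time(sub, days)
    for i, cpg in enumerate(sub.cpg_ids):
        x = sub.values[i]
        expected = stats.pearsonr(x, days).statistic if np.std(x) > 0 else 0.0
        assert np.isclose(r[cpg], expected, atol=1e-10)
    hyper, hypo = dc.select_drift_cpgs(r)
    brute_hyper = [c for c in sub.cpg_ids if r[c] > 0.9]
    assert hyper == brute_hyper
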