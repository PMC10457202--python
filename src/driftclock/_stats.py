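"""Two-group differential-methylation tests shared by the filtering stages.

The default test is a moderated t-test in the empirical-Bayes style used for
array differential analyses: per-CpG pooled variances are shrunk toward a
common prior fitted by method of moments to the distribution of log sample
variances (a scaled inverse-chi-square prior), which stabilises the statistic
for the small group sizes typical of sorted-cell reference sets.  A plain
Welch t-test is available as a fallback.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .io_core import DriftClockError


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Models the per-CpG pooled variances as ``s2 ~ s0^2 * F(df, d0)`` and
    returns ``(d0, s0sq)``.  ``d0 = inf`` when the observed spread of
    log-variances is no larger than expected from sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.median(s2)) if s2.size else 1e-8
    z = np.log(s2)
    e_bias = special.digamma(df / 2.0) - np.log(df / 2.0)
    mean_z = z.mean()
    var_z = z.var(ddof=1)
    excess = var_z - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(mean_z - e_bias))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = np.exp(
        mean_z - e_bias + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    )
    return float(d0), float(s0sq)


def two_group_test(
    a: np.ndarray,
    b: np.ndarray,
    method: str = "moderated",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row two-sided two-sample test between column groups ``a`` and ``b``.

    Parameters
    ----------
    a, b
        Arrays of shape (n_cpgs, n_a) and (n_cpgs, n_b); NaNs are not
        supported here (filter beforehand).
    method
        ``"moderated"`` (empirical-Bayes shrunken pooled variance) or
        ``"welch"``.

    Returns
    -------
    delta, t, p
        ``delta = mean(b) - mean(a)`` per row, the t statistic and the
        two-sided p-value.  A row with zero variance in both groups and equal
        means gets p = 1 by convention.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise DriftClockError("each group needs >= 2 samples")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    delta = mean_b - mean_a

    if method == "welch":
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
        t, p = np.asarray(t, float), np.asarray(p, float)
        degenerate = ~np.isfinite(t)
        t[degenerate] = 0.0
        p[degenerate] = np.where(np.isclose(delta[degenerate], 0.0), 1.0, 0.0)
        return delta, t, p
    if method != "moderated":
        raise DriftClockError(f"unknown test method {method!r}")

    df = n_a + n_b - 2.0
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / df
    d0, s0sq = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[degenerate] = np.where(np.isclose(delta[degenerate], 0.0), 1.0, 0.0)
    return delta, t, p
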