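"""Screening for cultivation-time-associated CpGs.

Candidate drift CpGs are those whose β values correlate almost linearly with
days in culture (|Pearson r| above a high threshold, default 0.9, strict
inequality).  Candidates that also track chronological donor age in an
external blood reference (|r| > 0.3) are removed, so the final set reflects
culture expansion rather than donor age.  A day-0 vs day-22 differential
methylation contrast (|Δβ| > 20% and BH-adjusted p < 0.05) summarises the
magnitude of the culture effect.

Each hybridised sample — not each donor — is one observation in the time
correlation; donor clustering is deliberately ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, two_group_test
from .io_core import BetaMatrix, DriftClockError


@dataclass
class DriftScreenResult:
    """Outcome of the correlation screen plus age exclusion."""

    r: pd.Series
    candidate_hyper: list[str]
    candidate_hypo: list[str]
    age_excluded: list[str] = field(default_factory=list)

    @property
    def final(self) -> list[str]:
        removed = set(self.age_excluded)
        return [c for c in self.candidate_hyper + self.candidate_hypo
                if c not in removed]


def correlate_with_time(beta: BetaMatrix, days) -> pd.Series:
    """Per-CpG Pearson correlation of β with days in culture.

    Missing β values are handled pairwise-complete; a CpG with fewer than 3
    complete pairs gets r = NaN and a warning.  Zero-variance CpGs get r = 0
    by convention.
    """
    days = np.asarray(days, dtype=float)
    if days.size != len(beta.sample_ids):
        raise DriftClockError("days must align with beta sample columns")
    if days.size < 3 or np.unique(days).size < 2:
        raise DriftClockError("no time gradient: need >=3 samples with distinct days")

    x = beta.values
    mask = np.isfinite(x)
    n = mask.sum(axis=1).astype(float)

    xz = np.where(mask, x, 0.0)
    sy = mask @ days
    sy2 = mask @ (days**2)
    sx = xz.sum(axis=1)
    sx2 = (xz**2).sum(axis=1)
    sxy = xz @ days

    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        var_x = sx2 - sx**2 / n
        var_y = sy2 - sy**2 / n
        r = cov / np.sqrt(var_x * var_y)
    # numerical slop can push |r| marginally past 1
    r = np.clip(r, -1.0, 1.0)
    zero_var = np.isclose(var_x, 0.0, atol=1e-16) | np.isclose(var_y, 0.0, atol=1e-16)
    r[zero_var & (n >= 3)] = 0.0
    low = n < 3
    r[low] = np.nan
    if low.any():
        ids = [beta.cpg_ids[i] for i in np.flatnonzero(low)[:10]]
        warnings.warn(f"{int(low.sum())} CpGs dropped (<3 complete pairs), e.g. {ids}")
    return pd.Series(r, index=beta.cpg_ids, name="r")


def select_drift_cpgs(r: pd.Series, r_hi: float = 0.9) -> tuple[list[str], list[str]]:
    """Split candidates into hyper (r > r_hi) and hypo (r < -r_hi) sets.

    Inequalities are strict: a CpG at exactly r = r_hi is not selected.
    """
    hyper = r.index[r > r_hi].tolist()
    hypo = r.index[r < -r_hi].tolist()
    return hyper, hypo


def exclude_age_cpgs(
    candidates,
    age_beta: BetaMatrix,
    ages,
    r_age: float = 0.3,
) -> tuple[list[str], list[str]]:
    """Remove candidates correlated with chronological age in a reference set.

    A candidate with |Pearson r(β, age)| > ``r_age`` in the age-reference
    matrix is removed.  Candidates absent from the reference are kept with a
    warning.
    """
    candidates = [str(c) for c in candidates]
    ages = np.asarray(ages, dtype=float)
    if len(age_beta.sample_ids) < 10:
        raise DriftClockError("age reference needs >= 10 samples")
    if np.unique(ages).size < 2:
        raise DriftClockError("all reference ages identical")
    present = [c for c in candidates if c in set(age_beta.cpg_ids)]
    absent = [c for c in candidates if c not in set(age_beta.cpg_ids)]
    if absent:
        warnings.warn(
            f"{len(absent)} candidate CpGs absent from age reference, kept: "
            f"{absent[:10]}"
        )
    removed: list[str] = []
    if present:
        sub = age_beta.select_cpgs(present)
        r = correlate_with_time(sub, ages)  # same estimator, age as the gradient
        removed = r.index[r.abs() > r_age].tolist()
    kept = [c for c in candidates if c not in set(removed)]
    return kept, removed


def differential_methylation(
    beta: BetaMatrix,
    group_a,
    group_b,
    delta: float = 0.20,
    alpha: float = 0.05,
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-CpG differential methylation between two sample groups.

    Returns a table with the mean difference (group_b − group_a), BH-adjusted
    p-value, direction (hyper if group_b > group_a) and a ``significant``
    column requiring BOTH |Δmean| > ``delta`` AND adjusted p < ``alpha``.
    """
    a = beta.select_samples(list(group_a)).values
    b = beta.select_samples(list(group_b)).values
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DriftClockError("each group needs >= 2 samples")
    d, t, p = two_group_test(a, b, method=method)
    p_adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "delta_mean": d,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(d > 0, "hyper", "hypo"),
        },
        index=pd.Index(beta.cpg_ids, name="cpg_id"),
    )
    out["significant"] = (out["delta_mean"].abs() > delta) & (out["p_adj"] < alpha)
    return out


def screen_drift_cpgs(
    beta: BetaMatrix,
    days,
    age_beta: BetaMatrix | None = None,
    ages=None,
    r_hi: float = 0.9,
    r_age: float = 0.3,
) -> DriftScreenResult:
    """Full screen: time correlation, threshold selection, age exclusion."""
    r = correlate_with_time(beta, days)
    hyper, hypo = select_drift_cpgs(r, r_hi=r_hi)
    age_excluded: list[str] = []
    if age_beta is not None:
        if ages is None:
            raise DriftClockError("ages required with age_beta")
        _, age_excluded = exclude_age_cpgs(hyper + hypo, age_beta, ages, r_age=r_age)
    return DriftScreenResult(r, hyper, hypo, age_excluded)
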