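"""Survival analysis of culture-associated methylation in clinical products.

Per-CpG multivariate Cox proportional-hazards screening (β rescaled ×10 so a
unit is 10% DNAm, adjusted for clinical trial and disease type, Efron tie
handling, Wald p-values), selection of survival-associated CpGs (HR > 1,
p < 0.01, deliberately unadjusted for multiple testing across the screen),
Cox models on predicted culture time (HR per predicted day), stratified
identification/validation cohort splitting, Kaplan–Meier stratification with
log-rank tests, and Student's t comparisons of toxicity groups (CRS/ICANS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from ._stats import bh_adjust
from .io_core import BetaMatrix, DriftClockError, SampleSheet


@dataclass
class SurvivalData:
    """Right-censored outcomes plus the two clinical covariates."""

    os_time: np.ndarray
    os_event: np.ndarray
    trial: np.ndarray
    disease: np.ndarray

    def __post_init__(self) -> None:
        self.os_time = np.asarray(self.os_time, dtype=float)
        self.os_event = np.asarray(self.os_event, dtype=int)
        self.trial = np.asarray([str(t) for t in self.trial])
        self.disease = np.asarray([str(d) for d in self.disease])
        n = self.os_time.size
        if not (self.os_event.size == self.trial.size == self.disease.size == n):
            raise DriftClockError("survival fields must have equal length")
        if (self.os_time <= 0).any():
            raise DriftClockError("os_time must be > 0")
        if not set(np.unique(self.os_event)) <= {0, 1}:
            raise DriftClockError("os_event must be 0/1")
        if self.os_event.sum() == 0:
            raise DriftClockError("no events: cannot fit Cox models")

    def __len__(self) -> int:
        return self.os_time.size

    @classmethod
    def from_sample_sheet(cls, sheet: SampleSheet) -> "SurvivalData":
        df = sheet.data
        ok = df["os_time"].notna()
        sub = df.loc[ok]
        return cls(sub["os_time"], sub["os_event"], sub["trial"], sub["disease"])

    def covariate_frame(self) -> pd.DataFrame:
        """Dummy-coded trial/disease (first level reference), constants dropped."""
        df = pd.DataFrame({"trial": self.trial, "disease": self.disease})
        out = pd.DataFrame(index=df.index)
        for col in ("trial", "disease"):
            levels = sorted(df[col].unique())
            if len(levels) == 1:
                warnings.warn(f"covariate {col!r} is constant and was dropped")
                continue
            for lev in levels[1:]:
                out[f"{col}_{lev}"] = (df[col] == lev).astype(float)
        return out


def _fit_cox(df: pd.DataFrame, focus: str) -> dict:
    """One Cox PH fit; returns the focus covariate's summary row."""
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="os_time", event_col="os_event")
        row = cph.summary.loc[focus]
        return {
            "coef": float(row["coef"]),
            "hr": float(row["exp(coef)"]),
            "ci_low": float(row["exp(coef) lower 95%"]),
            "ci_high": float(row["exp(coef) upper 95%"]),
            "p": float(row["p"]),
            "converged": True,
        }
    except Exception as exc:  # convergence failures flagged, not dropped
        warnings.warn(f"Cox fit failed for {focus!r}: {exc}")
        return {"coef": np.nan, "hr": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "p": np.nan, "converged": False}


def cox_screen_cpgs(
    beta: BetaMatrix,
    surv: SurvivalData,
    add_bh_column: bool = True,
) -> pd.DataFrame:
    """Per-CpG Cox screen: HR per 10% DNAm, adjusted for trial and disease.

    One model per CpG with the β value ×10 as continuous covariate plus the
    dummy-coded clinical covariates; Wald two-sided p.  Samples with missing
    β at a CpG are dropped for that CpG's fit.  ``q_bh`` is reported for
    transparency only — selection downstream is unadjusted.
    """
    if len(surv) != len(beta.sample_ids):
        raise DriftClockError("survival data must align with beta sample columns")
    covs = surv.covariate_frame()
    base = pd.DataFrame({"os_time": surv.os_time, "os_event": surv.os_event})
    base = pd.concat([base, covs], axis=1)
    rows = []
    for i, cpg in enumerate(beta.cpg_ids):
        df = base.copy()
        df.insert(0, "meth10", 10.0 * beta.values[i])
        df = df.dropna(subset=["meth10"])
        if df["os_event"].sum() == 0 or df["meth10"].nunique() <= 1:
            rows.append({"cpg_id": cpg, "coef": np.nan, "hr": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "converged": False})
            continue
        rows.append({"cpg_id": cpg, **_fit_cox(df, "meth10")})
    table = pd.DataFrame(rows).set_index("cpg_id")
    if add_bh_column:
        table["q_bh"] = bh_adjust(table["p"].to_numpy())
    return table


def select_survival_cpgs(
    table: pd.DataFrame, hr_min: float = 1.0, p_max: float = 0.01
) -> list[str]:
    """CpGs with HR > ``hr_min`` and Wald p < ``p_max`` (unadjusted)."""
    warnings.warn(
        "selection is not adjusted for multiple testing across the screen; "
        "see the q_bh column for BH-adjusted values"
    )
    hit = (table["hr"] > hr_min) & (table["p"] < p_max)
    return table.index[hit.fillna(False)].tolist()


def cox_on_prediction(predicted_days, surv: SurvivalData) -> dict:
    """Cox model of survival on predicted culture time (HR per day),
    adjusted for trial and disease."""
    pred = np.asarray(predicted_days, dtype=float)
    if pred.size != len(surv):
        raise DriftClockError("predictions must align with survival data")
    df = pd.DataFrame({"predicted_days": pred,
                       "os_time": surv.os_time, "os_event": surv.os_event})
    df = pd.concat([df, surv.covariate_frame()], axis=1).dropna(
        subset=["predicted_days"])
    return _fit_cox(df, "predicted_days")


def _age_tertiles(age: pd.Series) -> pd.Series:
    present = age.dropna()
    if present.nunique() < 3:
        return age.notna().map({True: "age_known", False: "age_missing"})
    q1, q2 = present.quantile([1 / 3, 2 / 3])
    def bin_one(v):
        if pd.isna(v):
            return "age_missing"
        if v <= q1:
            return "age_low"
        if v <= q2:
            return "age_mid"
        return "age_high"
    return age.map(bin_one)


def split_cohorts(
    sheet: SampleSheet,
    n_identification: int = 82,
    n_validation: int = 32,
    strata: list[str] | None = None,
    seed: int = 0,
) -> SampleSheet:
    """Stratified random split into identification/validation cohorts.

    Patients are grouped by the cross-classification of the given categorical
    strata columns (an ``age`` column is binned into tertiles first); each
    stratum contributes proportionally to both cohorts, with remainders
    assigned by seeded largest-remainder lottery.  Strata with fewer than two
    patients are merged into the nearest stratum (fewest differing
    components; ties to the largest), with a warning.  Patients beyond
    ``n_identification + n_validation`` stay unassigned.
    """
    df = sheet.data.copy()
    n = len(df)
    if n_identification + n_validation > n:
        raise DriftClockError("n_identification + n_validation exceeds patients")
    rng = np.random.default_rng(seed)

    if strata:
        keys = []
        for col in strata:
            if col == "age":
                keys.append(_age_tertiles(pd.to_numeric(df["age"], errors="coerce")))
            else:
                keys.append(df[col].astype(str).fillna("missing"))
        key_frame = pd.concat(keys, axis=1)
        labels = key_frame.apply(lambda row: "|".join(row.astype(str)), axis=1)
        # merge undersized strata
        counts = labels.value_counts()
        small = [lab for lab, c in counts.items() if c < 2]
        big = [lab for lab in counts.index if lab not in small]
        if small and not big:
            warnings.warn("all strata undersized; falling back to a single stratum")
            labels[:] = "all"
        else:
            for lab in small:
                parts = lab.split("|")
                def distance(other):
                    return sum(p != q for p, q in zip(parts, other.split("|")))
                target = min(big, key=lambda o: (distance(o), -counts[o]))
                warnings.warn(f"stratum {lab!r} has <2 patients; merged into {target!r}")
                labels[labels == lab] = target
    else:
        labels = pd.Series("all", index=df.index)

    def largest_remainder(sizes: pd.Series, total: int) -> pd.Series:
        exact = sizes / sizes.sum() * total
        base = np.floor(exact).astype(int)
        short = total - base.sum()
        frac = exact - base
        order = np.lexsort((rng.random(len(sizes)), -frac.to_numpy()))
        out = base.copy()
        for i in order[:short]:
            out.iloc[i] += 1
        return out

    sizes = labels.value_counts()
    quota_id = largest_remainder(sizes, n_identification)
    # validation quota proportional to what remains per stratum
    remaining = sizes - quota_id
    if remaining.sum() < n_validation:
        raise DriftClockError("validation quota exceeds remaining patients")
    quota_val = largest_remainder(remaining.clip(lower=0), n_validation)
    quota_val = np.minimum(quota_val, remaining)
    shortfall = n_validation - int(quota_val.sum())
    if shortfall > 0:
        room = (remaining - quota_val).sort_values(ascending=False)
        for lab in room.index:
            take = min(shortfall, int(room[lab]))
            quota_val[lab] += take
            shortfall -= take
            if shortfall == 0:
                break

    cohort = pd.Series("unassigned", index=df.index)
    for lab in sizes.index:
        members = np.flatnonzero((labels == lab).to_numpy())
        rng.shuffle(members)
        k_id, k_val = int(quota_id[lab]), int(quota_val[lab])
        cohort.iloc[members[:k_id]] = "identification"
        cohort.iloc[members[k_id:k_id + k_val]] = "validation"
    df["cohort"] = cohort
    return SampleSheet(df)


def km_stratify(values, surv: SurvivalData, mode: str = "quartiles") -> dict:
    """Kaplan–Meier curves and log-rank test across score-defined groups.

    ``mode="quartiles"`` cuts at the empirical quartiles (ties to the lower
    group); ``mode="median"`` gives a low/high split.  Returns
    ``{"groups", "curves", "logrank_p"}`` with one (time, survival, at_risk)
    table per group.
    """
    v = np.asarray(values, dtype=float)
    if v.size != len(surv):
        raise DriftClockError("values must align with survival data")
    if mode == "quartiles":
        if v.size < 8:
            raise DriftClockError("quartile stratification needs >= 8 patients")
        qs = np.quantile(v, [0.25, 0.5, 0.75])
        labels = np.array(["Q1", "Q2", "Q3", "Q4"])
    elif mode == "median":
        qs = np.quantile(v, [0.5])
        labels = np.array(["low", "high"])
    else:
        raise DriftClockError(f"unknown stratification mode {mode!r}")
    groups = labels[np.searchsorted(qs, v, side="left")]

    used = [lab for lab in labels if (groups == lab).any()]
    if len(used) < len(labels):
        warnings.warn(
            f"empty groups after ties merged away: kept {used}"
        )
    if len(used) < 2:
        raise DriftClockError("fewer than 2 non-empty groups; cannot stratify")

    curves = {}
    for lab in used:
        sel = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(surv.os_time[sel], surv.os_event[sel], label=str(lab))
        tab = kmf.event_table
        curves[lab] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_[str(lab)].to_numpy(),
            "at_risk": tab["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
        })
    res = multivariate_logrank_test(surv.os_time, groups, surv.os_event)
    return {"groups": pd.Series(groups), "curves": curves,
            "logrank_p": float(res.p_value)}


def compare_toxicity_groups(predicted_days, flags) -> float:
    """Two-sided pooled-variance Student's t-test of predicted culture time
    between toxicity flag groups (e.g. CRS yes/no)."""
    pred = np.asarray(predicted_days, dtype=float)
    fl = np.asarray(flags)
    ok = np.isfinite(pred) & pd.notna(fl)
    pred, fl = pred[ok], fl[ok].astype(int)
    a, b = pred[fl == 0], pred[fl == 1]
    if a.size == 0 or b.size == 0:
        raise DriftClockError("both toxicity groups must be non-empty")
    if a.size < 2 or b.size < 2:
        raise DriftClockError("a toxicity group of size 1 cannot be tested")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    t = stats.ttest_ind(a, b, equal_var=True)
    return float(t.pvalue)
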