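"""Synthetic cohorts with the statistical structure the pipeline assumes.

Generates (i) culture-expansion cohorts — β matrices over timepoints × donors
with planted near-linear drift CpGs, donor-age-correlated CpGs and
CD4/CD8-composition-confounded CpGs under additive Gaussian noise; (ii)
clinical cohorts — per-patient β profiles at trial-specific nominal culture
days plus a patient-intrinsic drift offset, with exponential survival whose
log-hazard is linear in β at a subset of drift CpGs; and (iii) per-read
amplicon call matrices interpolating between independent-Bernoulli and
comonotone (single shared latent threshold per read) models.

Every planted feature is returned as ground truth so recovery can be tested.
β noise is additive Gaussian with clipping to [0,1] rather than logit-normal:
simple, bounded, and matching the near-linear β trajectories the drift
screen targets; means near 0/1 are biased toward the interior by the
clipping.  The same seed always reproduces the same cohort bit-for-bit, and
culture and clinical cohorts generated from the same config share one CpG
universe (baselines and planted identities), so clocks trained on the former
transfer to the latter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io_core import BetaMatrix, DriftClockError, SampleSheet
from .readlevel import ReadSet

_CLIP_MARGIN = 0.05


@dataclass
class SurvivalConfig:
    """Clinical-cohort block: hazard structure and censoring.

    ``log_hr_per_10pct`` is the Cox log hazard ratio per 10% DNAm at each
    hazard CpG (a subset of the planted hyper-drift CpGs); ``trial_nominal_days``
    mirrors the manufacturing regimens of the three trials the clinical data
    come from (9–10 d IL-2, 7–10 d IL-7/IL-15, 14 d IL-7/IL-15).
    """

    n_patients: int = 200
    n_hazard_cpgs: int = 5
    log_hr_per_10pct: float = 0.4
    baseline_hazard: float = 0.002   # events per day at linear predictor 0
    censor_rate: float = 0.3
    drift_offset_sd: float = 2.0     # days; patient-intrinsic culture variation
    trial_nominal_days: dict = field(
        default_factory=lambda: {"trial_A": 9.5, "trial_B": 8.5, "trial_C": 14.0}
    )
    trial_effects: dict = field(
        default_factory=lambda: {"trial_A": 0.0, "trial_B": 0.15, "trial_C": -0.15}
    )
    disease_effects: dict = field(
        default_factory=lambda: {"ALL": 0.0, "NHL": 0.1}
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults emulate the profiling design the pipeline targets: four culture
    timepoints up to day 22 for ten donors, ~300 planted hypermethylating
    drift CpGs gaining 0.01 β/day, a handful of hypomethylating ones, and
    β noise with sd 0.02.
    """

    n_cpgs: int = 20_000
    timepoints: list[float] = field(default_factory=lambda: [0.0, 8.0, 15.0, 22.0])
    n_donors: int = 10
    n_drift_hyper: int = 300
    n_drift_hypo: int = 3
    drift_slope: float = 0.01        # Δβ per day
    n_age_cpgs: int = 10
    age_slope: float = 0.001         # Δβ per year
    n_comp_cpgs: int = 50
    comp_delta: float = 0.2          # Δβ between CD4 and CD8
    comp_traj_start: float = 0.6     # CD4 fraction at day 0
    comp_traj_slope: float = -0.015  # CD4 fraction change per day
    noise_sd: float = 0.02
    baseline_beta_a: float = 0.4     # Beta(a,b) baseline for unplanted CpGs
    baseline_beta_b: float = 0.4
    age_range: tuple[float, float] = (20.0, 60.0)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0
    #: optional separate seed for the sample/patient draw; the CpG universe
    #: (baselines, planted identities) stays tied to ``seed`` so replicate
    #: cohorts share one universe and trained clocks transfer across them
    cohort_seed: int | None = None

    def __post_init__(self) -> None:
        planted = self.n_drift_hyper + self.n_drift_hypo + self.n_age_cpgs + self.n_comp_cpgs
        if planted > self.n_cpgs:
            raise DriftClockError("planted CpG counts exceed n_cpgs")
        max_day = max(self.timepoints) if self.timepoints else 0.0
        if self.drift_slope * max_day >= 1.0 - 2 * _CLIP_MARGIN:
            raise DriftClockError(
                "drift_slope × max(day) leaves no room inside (0,1)"
            )
        if isinstance(self.survival, dict):
            self.survival = SurvivalConfig(**self.survival)
        if not 0.0 <= self.survival.censor_rate < 1.0:
            raise DriftClockError("censor_rate must be in [0,1)")

    @property
    def n_samples(self) -> int:
        return self.n_donors * len(self.timepoints)

    def comp_trajectory(self, day) -> np.ndarray:
        """CD4 (cell-type-1) fraction as a function of culture day."""
        return np.clip(self.comp_traj_start + self.comp_traj_slope * np.asarray(day, float),
                       0.05, 0.95)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    drift_hyper_ids: list[str]
    drift_hypo_ids: list[str]
    age_cpg_ids: list[str]
    comp_cpg_ids: list[str]
    hazard_cpg_ids: list[str] = field(default_factory=list)
    hazard_log_hr: dict[str, float] = field(default_factory=dict)
    true_days: dict[str, float] = field(default_factory=dict)
    true_cd4_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def drift_ids(self) -> list[str]:
        return self.drift_hyper_ids + self.drift_hypo_ids

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _cpg_universe(config: SimulationConfig, rng: np.random.Generator):
    """Per-CpG baselines, planted identities and signed slopes.

    Drawn from a dedicated seed stream so culture and clinical cohorts built
    from the same config share the same universe.  Age and composition sets
    are disjoint from the drift set; hazard CpGs are a subset of the hyper
    drift set by construction.
    """
    n = config.n_cpgs
    cpg_ids = [f"cg{i:06d}" for i in range(n)]
    max_day = max(config.timepoints)
    span = config.drift_slope * max_day

    baseline = rng.beta(config.baseline_beta_a, config.baseline_beta_b, size=n)
    baseline = np.clip(baseline, _CLIP_MARGIN, 1.0 - _CLIP_MARGIN)

    idx = rng.permutation(n)
    k = 0
    hyper = idx[k:k + config.n_drift_hyper]; k += config.n_drift_hyper
    hypo = idx[k:k + config.n_drift_hypo]; k += config.n_drift_hypo
    age = idx[k:k + config.n_age_cpgs]; k += config.n_age_cpgs
    comp = idx[k:k + config.n_comp_cpgs]

    # keep planted trajectories inside (0,1): rejection-free re-draw of baselines
    baseline[hyper] = rng.uniform(_CLIP_MARGIN, 1.0 - _CLIP_MARGIN - span,
                                  size=hyper.size)
    baseline[hypo] = rng.uniform(_CLIP_MARGIN + span, 1.0 - _CLIP_MARGIN,
                                 size=hypo.size)

    slope = np.zeros(n)
    slope[hyper] = config.drift_slope
    slope[hypo] = -config.drift_slope

    age_coef = np.zeros(n)
    age_coef[age] = config.age_slope * rng.choice([-1.0, 1.0], size=age.size)

    comp_coef = np.zeros(n)
    comp_coef[comp] = config.comp_delta * rng.choice([-1.0, 1.0], size=comp.size)

    hazard = hyper[:config.survival.n_hazard_cpgs]
    return {
        "cpg_ids": cpg_ids, "baseline": baseline, "slope": slope,
        "age_coef": age_coef, "comp_coef": comp_coef,
        "hyper": hyper, "hypo": hypo, "age": age, "comp": comp,
        "hazard": hazard,
    }


def _beta_values(config, uni, days, ages, rng):
    """β(cpg, sample) = clip(baseline + slope·day + age_term + comp_term + ε)."""
    days = np.asarray(days, float)
    ages = np.asarray(ages, float)
    mean_age = np.mean(config.age_range)
    f = config.comp_trajectory(days) - config.comp_trajectory(0.0)
    mean = (
        uni["baseline"][:, None]
        + uni["slope"][:, None] * days[None, :]
        + uni["age_coef"][:, None] * (ages[None, :] - mean_age)
        + uni["comp_coef"][:, None] * f[None, :]
    )
    noise = rng.normal(0.0, config.noise_sd, size=mean.shape) if config.noise_sd > 0 else 0.0
    return np.clip(mean + noise, 0.0, 1.0)


def _ground_truth(uni, config) -> GroundTruth:
    ids = uni["cpg_ids"]
    return GroundTruth(
        drift_hyper_ids=[ids[i] for i in uni["hyper"]],
        drift_hypo_ids=[ids[i] for i in uni["hypo"]],
        age_cpg_ids=[ids[i] for i in uni["age"]],
        comp_cpg_ids=[ids[i] for i in uni["comp"]],
        hazard_cpg_ids=[ids[i] for i in uni["hazard"]],
        hazard_log_hr={ids[i]: config.survival.log_hr_per_10pct
                       for i in uni["hazard"]},
    )


def simulate_culture_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, SampleSheet, GroundTruth]:
    """Timepoints × donors culture-expansion cohort with planted drift."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    rng_uni = np.random.default_rng(children[0])
    rng_samp = np.random.default_rng(
        children[1] if config.cohort_seed is None
        else np.random.SeedSequence([config.seed, int(config.cohort_seed), 1])
    )
    uni = _cpg_universe(config, rng_uni)

    donors = [f"donor{d:02d}" for d in range(config.n_donors)]
    donor_age = rng_samp.uniform(*config.age_range, size=config.n_donors)
    sample_ids, days, ages, donor_col = [], [], [], []
    for d, donor in enumerate(donors):
        for t in config.timepoints:
            sample_ids.append(f"{donor}_d{t:g}")
            days.append(float(t))
            ages.append(float(donor_age[d]))
            donor_col.append(donor)
    days, ages = np.asarray(days), np.asarray(ages)

    values = _beta_values(config, uni, days, ages, rng_samp)
    beta = BetaMatrix(uni["cpg_ids"], sample_ids, values)

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids, "donor_id": donor_col,
        "condition": "UT", "days_in_culture": days, "age": ages,
    }))
    truth = _ground_truth(uni, config)
    truth.true_days = dict(zip(sample_ids, days.tolist()))
    truth.true_cd4_fraction = dict(
        zip(sample_ids, config.comp_trajectory(days).tolist()))
    return beta, sheet, truth


def simulate_clinical_cohort(
    config: SimulationConfig, clock=None,
) -> tuple[BetaMatrix, SampleSheet, GroundTruth]:
    """Clinical CAR-T-product cohort with survival outcomes.

    Each patient receives a trial-specific nominal culture day plus a
    patient-intrinsic drift offset δᵢ ~ N(0, drift_offset_sd); the hazard is
    h₀·exp(Σⱼ bⱼ·10·βᵢⱼ + trial + disease) at the hazard CpGs, event times
    are exponential, and with probability ``censor_rate`` the observation is
    censored uniformly before the event.  If ``clock`` is given its
    predictions are added to the sample sheet as ``predicted_days``.
    """
    sc = config.survival
    children = np.random.SeedSequence(config.seed).spawn(3)
    rng_uni = np.random.default_rng(children[0])
    rng_pat = np.random.default_rng(
        children[2] if config.cohort_seed is None
        else np.random.SeedSequence([config.seed, int(config.cohort_seed), 2])
    )
    uni = _cpg_universe(config, rng_uni)

    n = sc.n_patients
    trials = list(sc.trial_nominal_days)
    diseases = list(sc.disease_effects)
    trial = rng_pat.choice(trials, size=n)
    disease = rng_pat.choice(diseases, size=n)
    delta = rng_pat.normal(0.0, sc.drift_offset_sd, size=n)
    eff_days = np.array([sc.trial_nominal_days[t] for t in trial]) + delta
    eff_days = np.clip(eff_days, 0.0, max(config.timepoints))
    ages = rng_pat.uniform(*config.age_range, size=n)

    values = _beta_values(config, uni, eff_days, ages, rng_pat)
    sample_ids = [f"patient{i:03d}" for i in range(n)]
    beta = BetaMatrix(uni["cpg_ids"], sample_ids, values)

    b = sc.log_hr_per_10pct
    lp = np.zeros(n)
    for i in uni["hazard"]:
        lp += b * 10.0 * values[i]
    lp -= lp.mean()  # centred so baseline_hazard is the typical-patient rate
    lp += np.array([sc.trial_effects[t] for t in trial])
    lp += np.array([sc.disease_effects[d] for d in disease])

    rate = sc.baseline_hazard * np.exp(lp)
    t_event = rng_pat.exponential(1.0 / rate)
    censored = rng_pat.random(n) < sc.censor_rate
    os_time = np.where(censored, rng_pat.uniform(0.0, 1.0, n) * t_event, t_event)
    os_time = np.maximum(os_time, 1e-6)
    os_event = (~censored).astype(int)

    df = pd.DataFrame({
        "sample_id": sample_ids, "condition": "CAR",
        "trial": trial, "disease": disease, "age": ages,
        "os_time": os_time, "os_event": os_event,
    })
    truth = _ground_truth(uni, config)
    truth.true_days = dict(zip(sample_ids, eff_days.tolist()))
    if clock is not None:
        from .clock import predict_days
        df["predicted_days"] = predict_days(clock, beta).to_numpy()
    sheet = SampleSheet(df)
    return beta, sheet, truth


def simulate_reads(
    mean_levels,
    n_reads: int = 1000,
    coherence: float = 0.0,
    seed: int = 0,
    amplicon_id: str = "amplicon",
    positions=None,
) -> ReadSet:
    """Per-read binary calls at the given per-CpG mean methylation levels.

    With probability ``coherence`` a read follows the comonotone model (one
    latent u ~ U(0,1) shared across its CpGs; CpG i methylated iff u < mᵢ),
    otherwise each CpG is an independent Bernoulli(mᵢ).  Both components
    preserve the marginal means, so E[β̂ᵢ] = mᵢ for every coherence level.
    """
    m = np.asarray(mean_levels, dtype=float)
    if ((m < 0) | (m > 1)).any() or not np.isfinite(m).all():
        raise DriftClockError("mean_levels must be in [0,1]")
    if not 0.0 <= coherence <= 1.0:
        raise DriftClockError("coherence must be in [0,1]")
    if n_reads < 1:
        raise DriftClockError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    comonotone = rng.random(n_reads) < coherence
    u = rng.random(n_reads)
    indep = rng.random((n_reads, m.size))
    calls = np.where(comonotone[:, None], u[:, None] < m[None, :],
                     indep < m[None, :]).astype(float)
    if positions is None:
        positions = list(range(1, m.size + 1))
    return ReadSet(amplicon_id, positions, calls)
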