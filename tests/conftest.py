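import numpy as np
import pytest

import driftclock as dc


@pytest.fixture(scope="session")
def small_culture():
    """Desk-scale culture cohort: 2000 CpGs, 50+3 planted drift, 40 samples."""
    cfg = dc.SimulationConfig(
        n_cpgs=2000, n_drift_hyper=50, n_drift_hypo=3,
        n_age_cpgs=5, n_comp_cpgs=10, seed=11,
    )
    beta, sheet, truth = dc.simulate_culture_cohort(cfg)
    return cfg, beta, sheet, truth


@pytest.fixture(scope="session")
def small_clock(small_culture):
    cfg, beta, sheet, truth = small_culture
    days = sheet.column("days_in_culture").to_numpy(float)
    cand = beta.select_cpgs(truth.drift_ids)
    model = dc.train_penalized_clock(cand, days, alpha=0.5, n_folds=5, seed=11)
    return model


@pytest.fixture(scope="session")
def small_clinical():
    """Clinical cohort of 120 patients with a real hazard signal."""
    cfg = dc.SimulationConfig(
        n_cpgs=500, n_drift_hyper=30, n_drift_hypo=3,
        n_age_cpgs=5, n_comp_cpgs=10, seed=7,
    )
    cfg.survival.n_patients = 120
    beta, sheet, truth = dc.simulate_clinical_cohort(cfg)
    surv = dc.SurvivalData.from_sample_sheet(sheet)
    return cfg, beta, sheet, truth, surv
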