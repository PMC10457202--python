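# driftclock

Culture-time epigenetic clocks and survival analysis for expanded (CAR) T
cells, built on DNA-methylation beta matrices.

## The problem

Manufacturing CAR T cell products requires culture expansion, and expanded T
cells accumulate DNA-methylation (DNAm) changes — a slow, stochastic
hypermethylation drift at specific CpG sites rather than coordinated
regulation of whole regions. The β value at a drifting CpG rises almost
linearly with days in culture, which makes these CpGs usable as an
*epigenetic clock* for culture time; and because products cultured for the
same nominal time still differ in how much drift they carry, the same
signature can capture product-intrinsic "loss of potential" that is
associated with patient survival after infusion.

`driftclock` implements that analysis end to end for anyone working with
methylation-array data from expanded T cells:

1. **Probe filtering** — remove CpGs with common SNPs (MAF > 1%), on
   chromosomes X/Y, cross-reactive probes, and CpGs confounded by the
   shifting CD4⁺/CD8⁺ ratio (differentially methylated between sorted CD4⁺
   and CD8⁺ cells: |Δβ| > 10% **or** BH-adjusted *p* < 0.05, moderated
   t-test).
2. **Drift screen** — per-CpG Pearson correlation of β with days in
   culture; candidates at *r* > 0.9 or *r* < −0.9 (strict), minus CpGs that
   track chronological donor age (|*r*| > 0.3) in a blood reference.
3. **Clock training** — elastic net (mixing α = 0.5, penalty λ by seeded
   10-fold CV, folds stratified by day) regressing days in culture on
   candidate-CpG β values; a ridge variant (α = 0) for small refined panels.
4. **Survival refinement** — per-CpG multivariate Cox models (hazard ratio
   per 10% DNAm, adjusted for clinical trial and disease, Efron ties, Wald
   *p*); CpGs with HR > 1 and *p* < 0.01 feed the ridge "loss-of-potential"
   predictor, evaluated by Cox on predicted days (HR per day), Kaplan–Meier
   stratification with log-rank tests, and Student's t comparisons of
   CRS/ICANS toxicity groups.
5. **Read-level coherence** — for bisulfite amplicons, pairwise phi
   coefficients between CpGs within reads, tested against a
   column-permutation null, to distinguish stochastic drift (incoherent
   reads) from targeted regulation (coherent reads).
6. **Deconvolution QC** — Houseman-style constrained least squares
   (f ≥ 0, Σf = 1) of cell-type fractions from reference profiles.
7. **Synthetic cohorts** — a generator that plants drift, age and
   composition CpGs and hazard-linked survival with full ground truth, so
   every stage is testable at desk scale.

## Worked example

```python
import driftclock as dc

# synthetic culture cohort: 4 timepoints (0/8/15/22 d) x 10 donors,
# 300 hyper- + 3 hypo-drifting CpGs planted among 20,000
cfg = dc.SimulationConfig(seed=2023)
beta, sheet, truth = dc.simulate_culture_cohort(cfg)
days = sheet.column("days_in_culture").to_numpy(float)

r = dc.correlate_with_time(beta, days)
hyper, hypo = dc.select_drift_cpgs(r)          # strict r > 0.9 / r < -0.9
print(len(hyper), len(hypo))                   # 300 3

cand = beta.select_cpgs(hyper + hypo)
model = dc.train_penalized_clock(cand, days, alpha=0.5, n_folds=10, seed=2023)
print(len(model.coefficients))                 # 299  (CpGs kept by the CV fit)

hold_beta, hold_sheet, _ = dc.simulate_culture_cohort(
    dc.SimulationConfig(seed=2023, n_donors=5, cohort_seed=777))
pred = dc.predict_days(model, hold_beta)
m = dc.evaluate_clock(pred.to_numpy(),
                      hold_sheet.column("days_in_culture").to_numpy(float))
print(round(m["r2"], 3), round(m["rmse"], 2))  # 1.0 0.15
```

The screen recovers exactly the planted 300 + 3 drift CpGs, and the clock
predicts held-out culture time with squared-Pearson r² ≈ 1 and an RMSE of
~0.15 days — i.e. at this noise level (β sd 0.02) culture time is read
almost perfectly off the drift CpGs. On a clinical-style cohort whose hazard
is tied to the drift level, `dc.cox_on_prediction` then yields HR > 1 per
predicted day (the loss-of-potential association).

The same flow is available from the shell:

```bash
driftclock simulate --out cohort/
driftclock screen --beta cohort/beta.tsv --samples cohort/samples.csv --out screen.json
driftclock train-clock --beta cohort/beta.tsv --samples cohort/samples.csv \
    --cpgs screen.json --out model.json
driftclock predict --model model.json --beta cohort/beta.tsv --out pred.csv
```

## Layout

- `src/driftclock/io_core.py` — beta matrix / sample sheet / probe
  annotation types and TSV/CSV round-trip IO
- `src/driftclock/synthetic_cohort.py` — cohort, survival and read simulators
- `src/driftclock/probe_filter.py`, `drift_screen.py` — filtering and screening
- `src/driftclock/clock.py` — penalized clocks (elastic net / ridge)
- `src/driftclock/survival.py` — Cox screen, cohort split, KM, toxicity tests
- `src/driftclock/readlevel.py` — per-read amplicon analysis
- `src/driftclock/deconvolution.py` — constrained-least-squares fractions
- `docs/methods.md` — model assumptions, parameter choices, limitations
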