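# resilac

Resilience indicators from daily milk yield, and their genetic analysis.

Dairy cows under automated milking produce a daily yield time series per
lactation. A resilient cow deviates little from her undisturbed production
trajectory when challenged (disease, heat stress, management upsets) and
recovers quickly; quantifying that from routinely recorded yields gives
breeders selectable resilience phenotypes without any extra recording.
`resilac` implements the full pipeline for researchers in dairy-cattle
breeding and quantitative genetics:

1. **Quality control** of raw daily records (DIM 1–305, 2.5–100 kg/day,
   de-duplication; lactation-level filters on age at first calving,
   observed-day counts and long gaps).
2. **Lactation clustering**: Z-score normalization, 24 decadal means over
   DIM 31–270, PCA (5 components), Ward agglomerative clustering with
   silhouette-based selection of the cluster count, and per-DIM 3-SD
   outlier removal within clusters.
3. **Imputation** to complete 305-day series: cluster-profile rule for the
   edges (DIM 1–4 and 305), then sequential linear-regression
   interpolation through days *n−4 … n−1, n+k*.
4. **Expected lactation curve (ELC)**: a weighted moving-average filter,
   four classical curve models —

   - Wood `Y(t) = a·t^b·e^{−ct}`
   - Nelder `1/Y(t) = a + b/t + c·t`
   - Wilmink `Y(t) = a + b·e^{−0.05t} + c·t`
   - Ali–Schaeffer `Y(t) = a + bt + ct² + d·ln t + e·(ln t)²`

   — best-R² model selection, then iterative deletion of days whose
   deviation falls below `LQ − 1.5·IQR` (low outliers only) until stable,
   with secondary QC (fitted values in (0, 100] kg, R² > 0.75).
5. **Resilience indicators** from the deviations `actual − ELC`:
   milk-loss traits built from *fluctuations* (≥ 10 consecutive days below
   the ELC, dipping below 90 % of it at least once) — per-event duration
   DML and loss MLF, per-lactation totals ML, NML, TDML and MLP — and
   variability traits Lnsd (log SD), Ra (lag-1 autocorrelation) and Ske
   (skewness) over four DIM windows (1–305, 11–295, 60–90,
   negative-deviation days).
6. **Quantitative genetics**: pedigree A-inverse (Henderson's rules,
   Meuwissen–Luo inbreeding), animal model `y = Xb + Za + e` with
   `a ~ N(0, A·σ²ₐ)`, repeatability and bivariate extensions, variance
   components by AI-REML (EM fallback, step-halving), BLUP breeding values
   with reliabilities `1 − PEV/σ²ₐ`, and a per-sire 80/20 birth-date
   validation split with top-vs-bottom-20 % EBV comparisons.
7. **Synthetic herd generator**: because real herd datasets of this kind
   are proprietary, `resilac.synthetic` simulates pedigrees, breeding
   values, lactation-shape archetypes, perturbation events and daily
   records with known ground truth, so every stage is testable end to end.

## Worked example

```python
import pandas as pd
from resilac import synthetic, preprocessing, clustering, imputation, elc, traits, quantgen

cfg = synthetic.SyntheticConfig(n_sires=10, n_daughters_per_sire=12, seed=42)
records, pedigree, truth = synthetic.simulate_dataset(cfg)

records, _ = preprocessing.filter_records(records)
lactations, _ = preprocessing.filter_lactations(records, birth_dates=pedigree.birth_dates)

model = clustering.cluster_lactations(lactations, k_range=range(2, 9))

rows = []
for lact in lactations:
    imputation.impute_lactation(lact, model.profile_for(lact))
    fit = elc.iterate_elc(lact.yields)
    if fit.qc_pass:
        row, events = traits.compute_phenotypes(lact, fit)
        rows.append(row)
phenotypes = pd.DataFrame(rows)
print(traits.summary_statistics(phenotypes, ["MY305", "NML", "ML", "MLP", "Lnsd2"]))

phenotypes, _ = traits.finalize_cohort(phenotypes, pedigree)
phenotypes = quantgen.add_model_factors(phenotypes)
vc = quantgen.reml_single(phenotypes, "Lnsd2", pedigree,
                          fixed_factors=("parity_class", "cluster"))
print(f"Lnsd2: h2 = {vc.h2:.3f} +/- {vc.se_h2:.3f}")
```

Output:

```
trait   N     mean      SD     min      max  CV_pct
MY305 170 11241.35 2965.26 6970.49 19570.44   26.38
  NML 170     1.70    1.17    0.00     5.00   68.88
   ML 170   240.37  250.10    0.00  1178.07  104.05
  MLP 170     2.11    2.03    0.00     9.59   96.22
Lnsd2 170     1.26    0.39    0.34     2.41   31.05
Lnsd2: h2 = 0.377 +/- 0.108
```

Reading the numbers: of 223 QC-passing lactations, 170 obtained an
acceptable expected curve. The average lactation loses ML ≈ 240 kg of milk
to perturbations, about MLP ≈ 2.1 % of its 305-day yield. `Lnsd2` is the
log-SD of the deviations over DIM 11–295 — the headline resilience
indicator (lower = more resilient) — and its heritability on this small
cohort, 0.38 ± 0.11, is within sampling noise of the generator's true
value of 0.25 (a 170-lactation cohort carries a large standard error; see
`docs/methods.md` for the calibrated 3,000-cow experiment).

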