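# fairdem

Fairness audit of dementia-prediction classifiers across socioeconomic and
sex subgroups.

Clinical risk models trained on electronic health records can perform worse
for socioeconomically deprived patients, whose records are often less
complete.  `fairdem` is a tested, reusable pipeline for quantifying and
mitigating that kind of algorithmic bias in one-year dementia-onset
prediction.  It is aimed at biostatisticians and clinical-informatics
researchers who have longitudinal visit records (or want a realistic
synthetic stand-in) and need a reproducible subgroup error audit.

## What it computes

The pipeline builds a case-control cohort from patient and visit tables:
each case's **index date** is set one year before the first dementia
diagnosis, controls receive index dates by age **frequency matching**, and
members without observation-window records or adequate follow-up are
excluded with a per-reason ledger.  Each member's 5-year observation window
is encoded as five annual diagnosis-category count blocks plus sex, age at
index, and five no-visit indicator flags.  Four classifier families (random
forest, logistic regression, RBF-kernel SVM, Gaussian naive Bayes) are
trained on a stratified 70/30 split with 5-fold cross-validated tuning.

The audit metric is the **balanced error rate**

```
BER = (FPR + FNR) / 2
```

computed per SES-by-sex stratum for each of three dichotomized SES measures
(an individual-level housing-based index and two area-deprivation indices),
with 1000-sample within-subgroup bootstrap 95% CIs, Levene-gated t tests on
the replicate vectors, Benjamini-Hochberg FDR control pooled per model, and
contrasts against the male/high-SES baseline.  Disparity is summarized by
the relative difference `(BER_low − BER_high) / BER_high`.

Bias mitigation is a from-scratch **SMOTE-NC** sampler applied to the
*protected attribute*: low-SES training rows are oversampled to parity with
the high-SES group, within each (SES × outcome) cell so the case/control
ratio is preserved, and never touching the test partition.

Because the source cohorts for this kind of study are access-restricted,
the package ships a seeded synthetic EHR generator whose defaults emulate
their published statistical structure: ~37% incident cases at population
scale (a research-panel preset has ~22%), three partially concordant SES
measures (low-SES prevalences 21%/5%/27%; cross-measure concordances
~12–40%), SES-graded visit missingness (mean missed years ~0.12 vs ~0.17
per 5-year window) and SES-graded category-recording dropout, and
case/control differences in visit rates and per-category prevalence.

## Worked example

```bash
fairdem run-all --n 2000 --seed 1 --fast \
    --families logistic_regression,naive_bayes --balance-measures m1 \
    --out demo
fairdem report --bundle-dir demo
```

prints (abridged):

```
"exclusion_ledger": {"age_lt_min": 0, "insufficient_followup": 9,
                     "no_observation_record": 0}
Relative BER differences (low vs high SES), by balancing regime:
        m1:logistic_regression  m1:naive_bayes  ...
none                  0.152210        0.194581  ...
m1                   -0.014992        0.156424  ...
```

Reading: with no mitigation, logistic regression's BER is 15.2% higher for
the low-SES group than the high-SES group on measure m1; after balancing
the training data on m1 the disparity essentially vanishes (−1.5%, a slight
inversion).  The per-subgroup table behind the first cell
(`demo/metrics_none_logistic_regression_m1.csv`) shows where the gap comes
from — mainly missed cases (higher FNR) among low-SES patients:

```
sex  ses      ber   ci_low  ci_high      fpr      fnr
all high 0.368998 0.323189 0.413517 0.272388 0.465608
all  low 0.425163 0.354986 0.496413 0.144444 0.705882
```

The same stages are available as library functions
(`fairdem.generate_population`, `build_cohort`, `build_feature_matrix`,
`tune_and_fit`, `subgroup_metrics`, `balance_protected`, `run_audit`) and as
scikit-learn-style estimators (`DementiaRiskClassifier`,
`ProtectedGroupSMOTENC`).

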