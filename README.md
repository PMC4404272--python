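# ntcp-lab

Normal tissue complication probability (NTCP) modelling of late
gastrointestinal toxicity after external-beam radiotherapy for localized
prostate cancer. The package is aimed at radiotherapy outcome modellers
and medical physicists who want to fit and compare dose-only and
dose-plus-clinical NTCP models on rectal dose-volume histograms (DVHs),
with honest uncertainty quantification.

## The models

**Lyman–Kutcher–Burman (LKB) with gEUD.** Each patient's rectal DVH is
reduced to a generalized equivalent uniform dose,

```
gEUD = ( Σᵢ vᵢ · dᵢ^(1/n) )ⁿ,
```

where `vᵢ` is the relative volume receiving dose `dᵢ` and `n ∈ (0, 1]`
is the volume-effect exponent (`n → 0`: serial organ, the maximum dose
dominates; `n = 1`: parallel organ, the mean dose). The complication
probability is a probit dose-response,

```
NTCP = Φ(t),   t = (gEUD − D₅₀) / (m · D₅₀),
```

with `D₅₀` the uniform dose giving 50% complication probability and `m`
the inverse slope. The triple `(D₅₀, m, n)` is estimated by maximizing
the Bernoulli log-likelihood of the observed binary outcomes with a
multistart Nelder–Mead simplex; uncertainty comes from fixed-nuisance
profile-likelihood intervals (threshold `LLH_max − χ²₁(0.95)/2`),
iso-likelihood contours in the three parameter planes, an NTCP
confidence bundle, and seeded bootstrap resampling.

**Multivariate logistic NTCP.** `NTCP = eᵍ/(1+eᵍ)` with
`g(x) = α + Σ βᵢxᵢ` over V65 (percentage of rectal volume receiving
≥ 65 Gy), antihypertensive/anticoagulant use (AH/AC) and acute GI
toxicity. The published 3-variable model
`g = −1.283 + 0.028·V65 − 1.442·AH/AC + 1.458·AcuteGI` ships as
`published_model()`; refitting on a cohort by maximum likelihood is one call.

Models are compared by paired ROC analysis: Mann–Whitney AUC with a
Hanley–McNeil confidence interval, the Youden-J optimal cutoff, the
DeLong Z-test for correlated ROC curves, and risk stratification of the
cohort at the cutoff.

Because no patient-level dataset is distributed, a synthetic cohort
generator (`ntcp_lab.synthetic_data`) reproduces the study conditions —
76 Gy in 2-Gy fractions, sigmoid-plus-plateau cumulative rectal DVHs,
AH/AC prevalence 66.7%, acute-toxicity prevalence 41.7%, and a late
toxicity rate calibrated to 25% under the default logistic truth model —
so every analysis is runnable and testable end to end.

## Worked example

```python
import numpy as np
from ntcp_lab import (
    generate_cohort, LKBProbitModel, published_model, logistic_ntcp,
    compare_auc_paired, profile_interval, fit_lkb,
)
from ntcp_lab.logistic import covariate_frame

cohort = generate_cohort(n_patients=500, truth_model="lkb", seed=11)

model = LKBProbitModel().fit(cohort.dvhs, cohort.outcomes)
print(f"D50 = {model.d50_:.1f} Gy, m = {model.m_:.3f}, n = {model.n_:.3f}, "
      f"LLH = {model.llh_:.1f}")

iv = profile_interval(cohort, model.result_, "d50")
print(f"D50 95% CI: {iv.lower:.1f}-{iv.upper:.1f} Gy")

X = covariate_frame(cohort)
ntcp_lkb = model.predict_proba(cohort.dvhs)[:, 1]
ntcp_log = logistic_ntcp(X, published_model())
cmp = compare_auc_paired(ntcp_lkb, ntcp_log, cohort.outcomes)
print(f"AUC LKB = {cmp.auc_a:.3f}, AUC logistic = {cmp.auc_b:.3f}, "
      f"z = {cmp.z:.2f}, p = {cmp.p_value:.3f}")
```

prints

```
D50 = 78.9 Gy, m = 0.140, n = 0.031, LLH = -268.5
D50 95% CI: 77.4-80.4 Gy
AUC LKB = 0.538, AUC logistic = 0.492, z = 1.17, p = 0.240
```

The fitted volume exponent is small — the rectum behaves serially for
this endpoint, so the high-dose tail of the DVH drives risk — and on
this cohort (whose outcomes were drawn from the weakly discriminating
LKB truth) neither model separates cases well, so the paired DeLong test
finds no significant AUC difference.

The same pipeline is available from the shell:

```sh
ntcp-lab simulate --n-patients 500 --seed 11 --out run/
ntcp-lab fit       --dvh-file run/dvh.csv --clinical-file run/clinical.csv --out run/
ntcp-lab bootstrap --dvh-file run/dvh.csv --clinical-file run/clinical.csv --n-runs 2000 --out run/
ntcp-lab compare   --dvh-file run/dvh.csv --clinical-file run/clinical.csv --out run/
ntcp-lab dx-curve  --dvh-file run/dvh.csv --clinical-file run/clinical.csv --out run/
```

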