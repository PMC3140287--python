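# thromboflap

A decision-analytic model of preoperative thrombophilia screening for
patients undergoing free tissue transfer (free-flap) surgery, written for
surgeons, hematologists and health-economics analysts who want to explore
when screen-and-treat strategies against thrombotic flap complications
become cost-effective.

## The problem and the model

Thrombosis of the microvascular anastomosis is the principal vascular
complication of free-flap surgery. Inherited and acquired thrombophilias
(factor V Leiden / activated protein C resistance, protein C/S and
antithrombin deficiencies, prothrombin G20210A, antiphospholipid
antibodies, hyperhomocysteinemia, factor VIII excess) affect a substantial
minority of the population and are usually undiagnosed, so some fraction of
"idiopathic" flap thromboses may be attributable to them — and preventable
with prophylactic anticoagulation in screen-positive patients.

The model partitions a cohort of N patients by thrombophilia carriage
(mutually exclusive, condition *i* with prevalence π_i). Each condition's
relative risk RR_i of a *first venous thromboembolism* serves as a proxy
for its relative risk of flap thrombosis, capped conservatively at a
per-carrier complication probability K:

    ρ_i = min(RR_i · p₀, K)

The unknown baseline per-case risk p₀ is calibrated so the cohort-average
risk equals the observed institutional complication rate r:

    Σ_i π_i · min(RR_i · p₀, K) + (1 − Σ_i π_i) · p₀ = r

From the calibrated model come per-condition expected complications
N·π_i·ρ_i, their screen-detectable subset (× assay sensitivity s_i), the
attributable fraction of complications, and four intervention scenarios —
baseline, full-panel screening, limited-panel screening, and universal
prophylaxis — each with per-patient cost affine in the complication cost C:

    cost(C) = S + A + X·C/N

Break-even points (the C at which a scenario's cost equals baseline's) and
incremental cost-effectiveness ratios (dollars per avoided complication;
ICER = C* − C) complete the economic comparison. A patient-level
Monte-Carlo simulator reproduces the same generative assumptions as a
cross-check, and synthetic-data generators provide registries, billing
pairs and panels with known ground truth for end-to-end testing.

The packaged default inputs are a 264-flap institutional registry (13
thrombotic complications, 4.9%; 5 flap losses, 1.9%), 13 matched
complicated/uncomplicated billing pairs (mean incremental direct cost
$23 246), and a 9-condition thrombophilia panel with prevalences, relative
risks, assay sensitivities and assay costs.

## Worked example

```python
from thromboflap import ScreeningModel, datasets

model = ScreeningModel(datasets.load_panel(), datasets.load_params())
res = model.fit()
print(res.summary())
```

prints (abridged):

```
Cohort size                          10,000
Observed complication rate           4.900%
Baseline per-case risk p0           0.01798
Risk cap active for              Antithrombin deficiency, Protein S deficiency

Expected screen positives            2888.5  (displayed 2889)
Attributable fraction                 73.8%
Absolute attributable rate             3.6%

Scenario economics (break-even to nearest $1000):
     scenario  ...  expected_complications_display  break_even      icer
     Baseline  ...                             490         NaN       NaN
   Full panel  ...                             172   57,000.00 33,707.00
Limited panel  ...                             213   39,000.00 15,755.00
  All therapy  ...                              59   49,000.00 25,455.00
```

Reading it: calibration puts the no-thrombophilia baseline risk at
p₀ ≈ 0.018 per case, with the 50% risk cap binding for the two rare,
high-relative-risk deficiencies. In a 10 000-patient cohort, 2889 patients
would screen positive, and ≈74% of the expected 490 thrombotic
complications are attributable to (detectable) thrombophilia. Screening
everyone with the full $1206 panel and treating positives with a $2100
prophylaxis course averts enough complications to break even once a
complication costs $57 000; a $572 limited panel (the top five conditions
by predicted detected complications, capturing ≈87% of them) breaks even
at $39 000; treating everyone without screening breaks even at $49 000.
At the observed $23 246 per complication, the cheapest route to one
avoided complication is the limited panel ($15 755 per complication
avoided).

The same analyses are available from the shell:

```bash
thromboflap registry-stats            # complication/failure rates
thromboflap cost-diff                 # billing-pair cost differential
thromboflap scenarios                 # scenario/break-even/ICER table
thromboflap sweep --cmax 70000 --plot breakeven.png
thromboflap simulate --n 1000000 --scenario all-therapy --seed 1
thromboflap reproduce --outdir out/   # all tables as TSV
```

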