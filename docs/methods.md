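# Methods

## The model

`thromboflap` implements a screen-and-treat decision model for thrombotic
complications of free tissue transfer. The clinical premise: a fraction of
"idiopathic" flap thromboses may be driven by undiagnosed thrombophilias,
and each thrombophilia's relative risk of a *first venous thromboembolism*
is used as a proxy for its relative risk of flap thrombosis.

A cohort of N patients is partitioned by thrombophilia carriage. Carriage
is mutually exclusive — each patient has at most one condition, condition
*i* with probability π_i and none with probability 1 − Σπ_i. This is why a
panel requires Σπ_i < 1 (the nine-condition default panel sums to 29.01%).
Coexistence of multiple thrombophilias is deliberately not modelled; there
is little data on coincidence rates, and ignoring it slightly undercounts
high-risk patients.

A non-carrier suffers a thrombotic complication with unknown baseline
probability p₀; a carrier of condition *i* with probability

    ρ_i = min(RR_i · p₀, K)

where K is a conservative per-condition risk cap (default 0.5: no
condition, however strong its relative risk, is allowed to push a carrier's
per-case probability past 50%). p₀ is not a free parameter — it is
calibrated so the cohort-average risk reproduces the observed institutional
complication rate r:

    Σ_i π_i · min(RR_i · p₀, K) + (1 − Σ_i π_i) · p₀ = r

The left side is continuous and strictly increasing in p₀ (the non-carrier
term always grows), so the root is unique. Because the cap introduces
piecewise-linear kinks, there is no single closed form; the root is found
by Brent's method on the bracket [0, r/(1 − Σπ_i)] with absolute tolerance
10⁻¹². When no cap binds the equation is linear and
p₀ = r / (Σπ_i·RR_i + 1 − Σπ_i); the solver is property-tested against this
closed form to 10⁻¹⁰ on random cap-free panels, and against an
independently coded bisection oracle otherwise. On the default inputs
p₀ ≈ 0.01798 and the cap binds for antithrombin deficiency and protein S
deficiency.

Per condition the model then reports expected carriers N·π_i, expected
complications M_i = N·π_i·ρ_i, *detected* complications D_i = s_i·M_i
(those among carriers the assay of sensitivity s_i would catch), and
expected test positives N·π_i·s_i. Conservation
Σ M_i + N·(1 − Σπ)·p₀ = N·r is asserted after every solve.

The attributable summary defaults to detected complications: the
attributable fraction is Σ D_i / (N·r) and the absolute rate Σ D_i / N
(≈ 73.8% and 3.62% on the default inputs). The variant on all carrier
complications M_i (ignoring detectability) is available via
`attributable(detected=False)`; with every assay at 100% sensitivity except
anticardiolipin (95%) the two differ little here.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `cohort_size` N | 10 000 | patients | theoretical cohort |
| `complication_rate` r | 0.049 | fraction | observed institutional thrombotic complication rate (13/264) |
| `risk_cap` K | 0.5 | probability | ceiling on any per-carrier risk |
| `therapy_efficacy` e | 0.88 | fraction | complications prevented by prophylactic enoxaparin |
| `therapy_cost` | $2100 | per treated patient | 30-day enoxaparin course |
| `complication_cost` | $23 246 | per event | incremental direct cost of one complication, from the matched billing pairs |
| `cancellation_rate` | 0 | fraction | positive screens never cancel surgery |

Panel CSVs and the params YAML carry percent units, matching how such
tables are printed; in-memory values are fractions, and the loaders are the
only place the factor of 100 appears.

## Scenarios, break-even and ICER

Four scenarios share the calibrated p₀. Per-patient accounting: screening
cost S is paid by every patient, therapy cost by expected test positives
only (everyone under all-therapy), and complications cost C each:

* Baseline: S = 0, A = 0, X = N·r.
* Screening over sub-panel P: S = Σ_{i∈P} c_i, A = C_rx·Σ_{i∈P} π_i·s_i,
  X = N·r − e·Σ_{i∈P} D_i. False negatives and carriers of unscreened
  conditions retain their full risk.
* All therapy: S = 0, A = C_rx, X = N·r·(1 − e).

Per-patient cost is affine in the complication cost,
cost(C) = S + A + X·C/N, with slope X/N. The break-even point of a
scenario versus baseline is

    C* = (S + A − S₀ − A₀) / ((X₀ − X)/N)

reported half-up to the nearest $1000 (the granularity at which such
figures are quoted); unrounded values are always exposed, because carrying
the printed integer complication counts instead of the unrounded
expectations shifts the full-panel break-even across a $1000 boundary. The
ICER at complication cost C is incremental cost per avoided complication
and satisfies the identity ICER = C* − C, which is property-tested on
random panels.

The limited panel is chosen by ranking conditions on predicted detected
complications (ties broken by cheaper assay, then name); the default top-5
panel costs $572 and captures ≈87% of detected complications.

## Display rounding

All intermediate quantities are unrounded; display rounding is half-up
(2888.5 → 2889), applied only in report tables: counts to integers,
currency to the dollar, break-even points to $1000.

## Known reconstruction discrepancies

The model is calibrated to its stated inputs, not to the printed output
tables, and three printed cells disagree slightly with the reconstruction:

* Lupus anticoagulant: with the tabulated RR of 11 the model predicts
  ≈49.4 detected complications; the printed column says 45 (consistent
  with RR 10). The printed column total (358) and attributable fraction
  (73%) consequently differ from the reconstruction (≈361.7, ≈73.8%).
* That row propagates into the full/limited scenario counts (printed
  171/212, reconstructed ≈171.7/≈213.0) and ICERs (printed
  $33 638/$15 617, reconstructed $33 707/$15 755) — all within 1%.
* Hyperhomocysteinemia: reconstruction 22.47 (displays 22), printed 23.
* The published per-patient scenario cost cells (e.g. $1067 baseline)
  cannot be reconciled with the corresponding complication counts at
  $23 246 per event (the formula gives $1139); the break-even and ICER
  figures, which *are* internally consistent with the formulas above, are
  reproduced instead. No parameter was adjusted to force cell-level
  agreement.

## Microsimulation

`simulate_cohort` draws each patient's condition from the categorical
{π_1…π_m, 1 − Σπ}, applies ρ_i (or p₀), tests screened carriers positive
with probability s_i (assay specificity is fixed at 1 — the panel has no
specificity column, so false positives and their therapy costs are out of
scope), multiplies treated patients' risk by 1 − e, and draws one Bernoulli
complication per patient; costs accumulate exactly as in the deterministic
accounting. Replicate *j* uses an independent generator seeded
`seed + j`, so results replay bit-identically. The simulator is used as a
brute-force oracle: at 10⁶ patients simulated rates match the
deterministic expectations within 3 binomial standard errors, and the
rate error decays as 1/√n (log–log slope checked over n = 10³…10⁶ with 16
replicates per size).

## Synthetic data

The generators emulate the *structure* of the institutional inputs, with
known ground truth:

* registries: categorical flap types, per-type complication Bernoullis,
  losses as a conditional Bernoulli given complication;
* billing pairs: lognormal comparator costs (right-skewed, positive
  support, median $22 000 and σ 0.45, chosen to span roughly
  $16k–$69k as the observed pairs do) plus a normal differential (mean
  $23 246, sd $20 000 by default) so negative differentials occur, as
  three observed pairs do. Index costs are truncated at $0; when the
  differential distribution places real mass below −comparator this
  truncation upward-biases the recovered mean differential — a property of
  the generator, not of the analysis;
* random panels for property tests: Σπ rescaled below 0.9, RR ∈ [1, 40],
  sensitivity ∈ (0.5, 1], assay cost ∈ [$20, $500].

What passing recovery tests show: the registry → summary and pairs →
differential pipelines are unbiased at the configured truth under the
generators' idealisations (independent cases, exact matching, no billing
outliers beyond lognormal tails). They do not validate the VTE-proxy
assumption, the mutual-exclusivity assumption, or transportability of the
4.9% rate — those are modelling choices, not estimable from synthetic data.

## Problem sizes and runtime

The deterministic analysis is closed-form plus one scalar root find and
runs in milliseconds. Test-suite simulation sizes were chosen so Monte-
Carlo checks are decisive (3–4 SE margins) while the whole suite stays in
seconds on one core: 10⁶ patients for rate checks, 2×10⁵ × 8 replicates
for per-condition and scenario checks, 200–500 seeds for generator
recovery.

## Limitations

Single perioperative episode; no discounting, no QALYs (the effect unit is
an avoided thrombotic flap complication); no bleeding-complication costs
from prophylaxis; no arterial/venous subtype distinction; assay
specificity fixed at 1; complication cost uniform across conditions;
relative risks are inputs, not estimated. The per-condition cap K is a
blunt conservatism — results for high-RR, low-prevalence conditions
(antithrombin, protein S deficiency) sit exactly at the cap and should be
read as bounded, not estimated.
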