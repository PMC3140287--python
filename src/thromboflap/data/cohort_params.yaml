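# Cohort-level model assumptions. Percentages are given in percent units,
# mirroring the printed table; loaders convert to fractions.
cohort_size: 10000
flap_cancellation_rate_pct: 0
therapy_cost: 2100
therapy_efficacy_pct: 88
complication_cost: 23246
complication_rate_pct: 4.9
risk_cap_pct: 50
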