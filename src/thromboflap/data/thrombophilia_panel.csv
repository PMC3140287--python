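name,prevalence_pct,relative_risk,sensitivity_pct,assay_cost
Activated protein C resistance,5.00,7.5,100,116
Anticardiolipin antibody,2.50,3.2,95,222
Antithrombin deficiency,0.17,28.2,100,96
Factor VIII excess,11.00,7.1,100,154
Hyperhomocysteinemia,5.00,2.5,100,137
Lupus anticoagulant,2.50,11.0,100,49
Protein C deficiency,0.14,24.1,100,114
Protein S deficiency,0.70,30.6,100,116
Prothrombin G20210A mutation,2.00,5.2,100,202
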