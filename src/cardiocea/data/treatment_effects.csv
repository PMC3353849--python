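comparison,outcome,population_variant,rr,ci_low,ci_high,provenance
ace_vs_ccb,total_mortality,all_included,1.05,0.98,1.11,meta
ace_vs_ccb,ami,all_included,0.97,0.84,1.13,meta
ace_vs_ccb,stroke,all_included,1.13,0.97,1.32,meta
ace_vs_ccb,heart_failure,all_included,0.85,0.78,0.94,meta
ace_vs_ccb,angina,all_included,1.07,0.99,1.17,meta
diuretic_vs_ace,total_mortality,all_included,1.00,0.95,1.07,meta
diuretic_vs_ace,ami,all_included,1.01,0.88,1.17,meta
diuretic_vs_ace,stroke,all_included,0.88,0.80,0.98,meta
diuretic_vs_ace,heart_failure,all_included,0.94,0.71,1.24,meta
diuretic_vs_ace,angina,all_included,0.91,0.85,0.98,meta
ace_vs_ccb,total_mortality,african_american_excluded,1.03,0.96,1.11,meta
ace_vs_ccb,ami,african_american_excluded,0.96,0.85,1.08,meta
ace_vs_ccb,stroke,african_american_excluded,1.04,0.92,1.19,meta
ace_vs_ccb,heart_failure,african_american_excluded,0.86,0.80,0.93,meta
ace_vs_ccb,angina,african_american_excluded,1.05,0.95,1.15,meta
diuretic_vs_ace,total_mortality,african_american_excluded,1.04,0.96,1.12,meta
diuretic_vs_ace,ami,african_american_excluded,1.02,0.93,1.12,meta
diuretic_vs_ace,stroke,african_american_excluded,0.98,0.86,1.12,meta
diuretic_vs_ace,heart_failure,african_american_excluded,0.97,0.90,1.05,meta
diuretic_vs_ace,angina,african_american_excluded,0.95,0.87,1.04,meta
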