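comparison,outcome,population_variant,rr,ci_low,ci_high,provenance
ccb_vs_placebo,total_mortality,all,0.89,0.81,0.98,synthetic
ccb_vs_placebo,ami,all,0.80,0.70,0.92,synthetic
ccb_vs_placebo,stroke,all,0.66,0.56,0.78,synthetic
ccb_vs_placebo,heart_failure,all,0.72,0.60,0.86,synthetic
ccb_vs_placebo,angina,all,0.90,0.78,1.04,synthetic
arb_vs_ccb,total_mortality,all,1.03,0.94,1.13,synthetic
arb_vs_ccb,ami,all,1.05,0.92,1.20,synthetic
arb_vs_ccb,stroke,all,0.98,0.86,1.12,synthetic
arb_vs_ccb,heart_failure,all,0.95,0.84,1.08,synthetic
arb_vs_ccb,angina,all,1.02,0.90,1.16,synthetic
beta_blocker_vs_ccb,total_mortality,all,1.08,0.98,1.19,synthetic
beta_blocker_vs_ccb,ami,all,1.10,0.96,1.26,synthetic
beta_blocker_vs_ccb,stroke,all,1.12,0.98,1.28,synthetic
beta_blocker_vs_ccb,heart_failure,all,1.05,0.91,1.21,synthetic
beta_blocker_vs_ccb,angina,all,1.00,0.88,1.14,synthetic
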