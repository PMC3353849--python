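primary_event,secondary_event,sex,age_low,age_high,value,ci_low,ci_high,period,provenance
angina,cvd_death,male,,,0.0108,0.0060,0.0156,one_year,registry
angina,cvd_death,female,,,0.0134,0.0071,0.0197,one_year,registry
angina,ami,male,,,0.0153,0.0096,0.0211,one_year,registry
angina,ami,female,,,0.0173,0.0101,0.0245,one_year,registry
angina,stroke,male,,,0.0119,0.0069,0.0170,one_year,registry
angina,stroke,female,,,0.0110,0.0053,0.0168,one_year,registry
angina,heart_failure,male,,,0.0153,0.0096,0.0211,one_year,registry
angina,heart_failure,female,,,0.0181,0.0108,0.0254,one_year,registry
ami,death,both,30,59,0.04,,,one_year,registry
ami,death,both,60,69,0.09,,,one_year,registry
ami,death,both,70,79,0.20,,,one_year,registry
ami,death,both,80,120,0.38,,,one_year,registry
nonstemi,angina,both,,,0.090,0.074,0.106,one_year,trial
nonstemi,heart_failure,both,,,0.246,0.235,0.256,in_hospital,registry
nonstemi,reinfarction,both,,,0.014,0.011,0.017,in_hospital,registry
nonstemi,stroke,both,,,0.018,0.015,0.020,six_months,registry
nonstemi,stroke,both,,,0.009,0.007,0.011,in_hospital,registry
stemi,angina,both,,,0.114,0.083,0.145,one_year,trial
stemi,heart_failure,both,,,0.288,0.277,0.298,in_hospital,registry
stemi,reinfarction,both,,,0.027,0.022,0.032,in_hospital,registry
stemi,stroke,both,,,0.021,0.018,0.023,six_months,registry
stemi,stroke,both,,,0.013,0.011,0.015,in_hospital,registry
reinfarction,death,both,,,0.242,0.135,0.349,thirty_days,trial
secondary_heart_failure,transient,both,,,0.500,0.333,0.750,one_year,expert
secondary_heart_failure,death,both,,,0.290,0.240,0.340,one_year,registry
primary_heart_failure,death,male,,,0.173,0.132,0.213,one_year,registry
primary_heart_failure,death,female,,,0.163,0.116,0.209,one_year,registry
stroke,death,both,,,0.338,0.315,0.361,one_year,registry
stroke,moderate_sequelae,both,,,0.072,0.060,0.084,one_year,registry
stroke,severe_sequelae,both,,,0.169,0.158,0.180,one_year,registry
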