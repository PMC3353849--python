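health_state,event,sex,age_low,age_high,year_band,rr,ci_low,ci_high,provenance
post_ami,ami,both,,,,3.05,1.47,4.60,trial
post_ami,angina,both,,,,21.7,15.8,27.6,trial
post_ami,death,both,30,59,,3.55,,,trial
post_ami,death,both,60,69,,2.36,,,trial
post_ami,death,both,70,120,,1.00,,,trial
post_ami,stroke,both,,,,2.77,2.08,3.47,trial
post_angina,ami,male,,,,3.88,2.24,5.60,trial
post_angina,ami,female,,,,1.17,0.76,1.59,trial
post_angina,angina,both,,,,11.32,8.30,14.29,report
post_angina,death,both,,,,1.23,0.82,1.65,report
post_angina,stroke,male,,,,5.34,,,report
post_angina,stroke,female,,,,5.26,,,report
post_stroke_no_sequelae,ami,both,,,,3.51,1.78,5.33,derived
post_stroke_no_sequelae,death,both,,,,4.91,3.86,5.97,derived
post_stroke_no_sequelae,stroke,both,,,,2.82,1.81,3.48,trial
heart_failure,death,female,,,second,6.67,6.16,11.04,registry
heart_failure,death,female,,,third,7.61,5.08,10.15,registry
heart_failure,death,female,,,later,2.45,0.90,4.00,registry
heart_failure,death,male,,,second,5.05,3.24,6.86,registry
heart_failure,death,male,,,third,4.62,2.90,6.33,registry
heart_failure,death,male,,,later,2.13,0.96,3.31,registry
heart_failure,stroke,both,,,,6.80,3.40,13.61,registry
heart_failure,hf_worsening,both,,,,9.58,9.04,10.13,registry
heart_failure,ami,male,,,,1.5,0.6,3.8,trial
heart_failure,ami,female,,,,4.1,1.8,9.3,registry
moderate_stroke_sequelae,ami,both,,,,4.41,3.32,5.28,study
moderate_stroke_sequelae,heart_failure,both,,,,2,1,4,study
moderate_stroke_sequelae,stroke,both,,,,4.30,3.92,4.62,meta
moderate_stroke_sequelae,death,both,,,,2,1.5,2.5,expert
severe_stroke_sequelae,death,both,,,,3,2.25,3.75,meta
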