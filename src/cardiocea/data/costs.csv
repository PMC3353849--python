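label,kind,value
angina_event,one_time_event,15242
post_ami_year,per_year_state,331
post_stroke_year,per_year_state,292
post_angina_year,per_year_state,292
cardiac_death_hospital,one_time_event,5169
heart_failure_event,one_time_event,1346
hf_worsening_event,one_time_event,4598
heart_failure_year,per_year_state,3569
moderate_stroke_sequelae_year,per_year_state,6436
nonstemi_event,one_time_event,22674
severe_stroke_sequelae_year,per_year_state,99875
reinfarction_event,one_time_event,3713
stemi_event,one_time_event,22674
stroke_event,one_time_event,23546
drg_unit,one_time_event,4615
gp_visits_statin_first_year,per_year_gp_visits,185
gp_visits_statin_later_years,per_year_gp_visits,94
gp_visits_thiazide_first_year,per_year_gp_visits,195
gp_visits_thiazide_later_years,per_year_gp_visits,97
thiazide_year,per_year_drug,20
ace_year,per_year_drug,58
ccb_year,per_year_drug,30
arb_year,per_year_drug,73
beta_blocker_year,per_year_drug,35
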