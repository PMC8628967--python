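variable,category,without_pip,with_pip
gender,female,187,791
gender,male,100,447
age_group,<=74,182,581
age_group,75-79,74,415
age_group,>=80,31,242
education,no_diploma_or_primary,59,275
education,secondary,95,416
education,high_school,51,167
education,university,77,361
intervention_group,multidomain_pufa,68,306
intervention_group,pufa,60,321
intervention_group,multidomain_placebo,83,307
intervention_group,placebo,76,304
polypharmacy,0-4,255,557
polypharmacy,5-9,32,557
polypharmacy,>=10,0,124
charlson,0,269,915
charlson,1,16,232
charlson,>=2,2,91
frailty,robust,187,612
frailty,prefrail,79,524
frailty,frail,5,38
iadl_deficit,no_deficit,277,1181
iadl_deficit,deficit,8,56
hypertension,present,157,857
hypertension,absent,130,381
myocardial_infarction,present,0,88
myocardial_infarction,absent,287,1150
heart_failure,present,2,65
heart_failure,absent,285,1173
peripheral_vascular_disease,present,3,43
peripheral_vascular_disease,absent,284,1195
cerebrovascular_accident_or_tia,present,1,41
cerebrovascular_accident_or_tia,absent,286,1197
copd,present,1,41
copd,absent,286,1197
peptic_ulcer,present,7,58
peptic_ulcer,absent,280,1180
diabetes,present,0,13
diabetes,absent,287,1225
severe_chronic_kidney_disease,present,1,7
severe_chronic_kidney_disease,absent,286,1231
cancer,present,0,9
cancer,absent,287,1229
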