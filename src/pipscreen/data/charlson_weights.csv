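condition,weight,citation
myocardial_infarction,1,original 1987 index
heart_failure,1,original 1987 index
peripheral_vascular_disease,1,original 1987 index
cerebrovascular_accident_or_tia,1,original 1987 index
copd,1,original 1987 index
peptic_ulcer,1,original 1987 index
diabetes,1,original 1987 index
dementia,1,original 1987 index
severe_chronic_kidney_disease,2,original 1987 index
cancer,2,original 1987 index
liver_failure,3,original 1987 index (moderate/severe liver disease)
severe_liver_disease,3,original 1987 index (moderate/severe liver disease)
metastatic_cancer,6,original 1987 index
aids,6,original 1987 index
hypertension,0,not scored
prostatism,0,not scored
prostatectomy,0,not scored
oesogastric_damage,0,not scored
osteoporosis,0,not scored
nephrotic_syndrome,0,not scored
renal_syndrome,0,not scored
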