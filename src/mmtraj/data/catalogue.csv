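code,name,resolvable,cluster
anxiety,Anxiety,0,A
depression,Depression,1,A
heart_failure,Heart failure,0,B
atrial_fibrillation,Atrial fibrillation,1,B
ckd,Chronic kidney disease,1,B
chd,Coronary heart disease,0,B
stroke_tia,Stroke or TIA,0,B
pad,Peripheral arterial disease,0,B
dementia,Dementia,0,B
osteoporosis,Osteoporosis,0,B
osteoarthritis,Osteoarthritis,0,C
cancer,Cancer,1,C
chronic_pain,Chronic pain,1,C
hypertension,Hypertension,1,C
diabetes_type2,Type 2 diabetes,1,C
chronic_liver_disease,Chronic liver disease,0,D
viral_hepatitis,Viral hepatitis,0,D
alcohol_dependency,Alcohol dependency,1,E
substance_dependency,Substance dependency,1,E
hiv,HIV,0,E
asthma,Asthma,1,F
copd,COPD,0,F
epilepsy,Epilepsy,1,F
morbid_obesity,Morbid obesity,1,F
ibd,Inflammatory bowel disease,0,F
lupus,Systemic lupus erythematosus,0,F
sickle_cell_disease,Sickle cell disease,0,F
serious_mental_illness,Serious mental illness,0,F
learning_disability,Learning disability,0,F
multiple_sclerosis,Multiple sclerosis,0,F
parkinsons_disease,Parkinson's disease,0,F
eating_disorder,Eating disorder,0,F
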