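# Default ICD-10 cause grouping for comorbid-condition analysis of
# dementia multiple-cause-of-death records.  Groups other than dementia are
# pairwise disjoint; "remainder" groups (other_cvd, other_respiratory,
# injuries) list their intervals with the carved-out sub-ranges excluded.
# Edit or replace this file to match a national grouping scheme.
dementia: [F00, F01, F03, G30, G31]
ischemic_heart_disease: [I20-I25]
stroke: [I60-I69]
other_cvd: [I00-I19, I26-I59, I70-I99]
cancers: [C00-C97]
pneumonia: [J12-J18]
chronic_respiratory: [J40-J47]
other_respiratory: [J00-J11, J19-J39, J48-J99]
ill_defined: [R00-R99]
renal: [N17-N19]
parkinson: [G20-G21]
urinary_tract_infection: [N39]
diabetes: [E10-E14]
falls: [W00-W19]
injuries: [V01-V99, W20-Y89]
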