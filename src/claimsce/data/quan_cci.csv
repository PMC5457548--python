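category,icd9_prefix,weight
myocardial_infarction,410,1
myocardial_infarction,412,1
congestive_heart_failure,398.91,1
congestive_heart_failure,402.01,1
congestive_heart_failure,402.11,1
congestive_heart_failure,402.91,1
congestive_heart_failure,404.01,1
congestive_heart_failure,404.03,1
congestive_heart_failure,404.11,1
congestive_heart_failure,404.13,1
congestive_heart_failure,404.91,1
congestive_heart_failure,404.93,1
congestive_heart_failure,425.4,1
congestive_heart_failure,425.5,1
congestive_heart_failure,425.6,1
congestive_heart_failure,425.7,1
congestive_heart_failure,425.8,1
congestive_heart_failure,425.9,1
congestive_heart_failure,428,1
peripheral_vascular,093.0,1
peripheral_vascular,437.3,1
peripheral_vascular,440,1
peripheral_vascular,441,1
peripheral_vascular,443.1,1
peripheral_vascular,443.2,1
peripheral_vascular,443.8,1
peripheral_vascular,443.9,1
peripheral_vascular,447.1,1
peripheral_vascular,557.1,1
peripheral_vascular,557.9,1
peripheral_vascular,V43.4,1
cerebrovascular,362.34,1
cerebrovascular,430,1
cerebrovascular,431,1
cerebrovascular,432,1
cerebrovascular,433,1
cerebrovascular,434,1
cerebrovascular,435,1
cerebrovascular,436,1
cerebrovascular,437,1
cerebrovascular,438,1
dementia,290,1
dementia,294.1,1
dementia,331.2,1
chronic_pulmonary,416.8,1
chronic_pulmonary,416.9,1
chronic_pulmonary,490,1
chronic_pulmonary,491,1
chronic_pulmonary,492,1
chronic_pulmonary,493,1
chronic_pulmonary,494,1
chronic_pulmonary,495,1
chronic_pulmonary,496,1
chronic_pulmonary,500,1
chronic_pulmonary,501,1
chronic_pulmonary,502,1
chronic_pulmonary,503,1
chronic_pulmonary,504,1
chronic_pulmonary,505,1
chronic_pulmonary,506.4,1
chronic_pulmonary,508.1,1
chronic_pulmonary,508.8,1
rheumatic,446.5,1
rheumatic,710.0,1
rheumatic,710.1,1
rheumatic,710.2,1
rheumatic,710.3,1
rheumatic,710.4,1
rheumatic,714.0,1
rheumatic,714.1,1
rheumatic,714.2,1
rheumatic,714.8,1
rheumatic,725,1
peptic_ulcer,531,1
peptic_ulcer,532,1
peptic_ulcer,533,1
peptic_ulcer,534,1
mild_liver,070.22,1
mild_liver,070.23,1
mild_liver,070.32,1
mild_liver,070.33,1
mild_liver,070.44,1
mild_liver,070.54,1
mild_liver,070.6,1
mild_liver,070.9,1
mild_liver,570,1
mild_liver,571,1
mild_liver,573.3,1
mild_liver,573.4,1
mild_liver,573.8,1
mild_liver,573.9,1
mild_liver,V42.7,1
diabetes_uncomplicated,250.0,1
diabetes_uncomplicated,250.1,1
diabetes_uncomplicated,250.2,1
diabetes_uncomplicated,250.3,1
diabetes_uncomplicated,250.8,1
diabetes_uncomplicated,250.9,1
diabetes_complicated,250.4,2
diabetes_complicated,250.5,2
diabetes_complicated,250.6,2
diabetes_complicated,250.7,2
hemiplegia,334.1,2
hemiplegia,342,2
hemiplegia,343,2
hemiplegia,344.0,2
hemiplegia,344.1,2
hemiplegia,344.2,2
hemiplegia,344.3,2
hemiplegia,344.4,2
hemiplegia,344.5,2
hemiplegia,344.6,2
hemiplegia,344.9,2
renal,403.01,2
renal,403.11,2
renal,403.91,2
renal,404.02,2
renal,404.12,2
renal,404.92,2
renal,582,2
renal,583.0,2
renal,583.1,2
renal,583.2,2
renal,583.4,2
renal,583.6,2
renal,583.7,2
renal,585,2
renal,586,2
renal,588.0,2
renal,V42.0,2
renal,V45.1,2
renal,V56,2
malignancy,140,2
malignancy,141,2
malignancy,142,2
malignancy,143,2
malignancy,144,2
malignancy,145,2
malignancy,146,2
malignancy,147,2
malignancy,148,2
malignancy,149,2
malignancy,150,2
malignancy,151,2
malignancy,152,2
malignancy,153,2
malignancy,154,2
malignancy,155,2
malignancy,156,2
malignancy,157,2
malignancy,158,2
malignancy,159,2
malignancy,160,2
malignancy,161,2
malignancy,162,2
malignancy,163,2
malignancy,164,2
malignancy,165,2
malignancy,170,2
malignancy,171,2
malignancy,172,2
malignancy,174,2
malignancy,175,2
malignancy,176,2
malignancy,179,2
malignancy,180,2
malignancy,181,2
malignancy,182,2
malignancy,183,2
malignancy,184,2
malignancy,185,2
malignancy,186,2
malignancy,187,2
malignancy,188,2
malignancy,189,2
malignancy,190,2
malignancy,191,2
malignancy,192,2
malignancy,193,2
malignancy,194,2
malignancy,195,2
malignancy,200,2
malignancy,201,2
malignancy,202,2
malignancy,203,2
malignancy,204,2
malignancy,205,2
malignancy,206,2
malignancy,207,2
malignancy,208,2
malignancy,238.6,2
severe_liver,456.0,3
severe_liver,456.1,3
severe_liver,456.2,3
severe_liver,572.2,3
severe_liver,572.3,3
severe_liver,572.4,3
severe_liver,572.8,3
metastatic,196,6
metastatic,197,6
metastatic,198,6
metastatic,199,6
hiv_aids,042,6
hiv_aids,043,6
hiv_aids,044,6
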