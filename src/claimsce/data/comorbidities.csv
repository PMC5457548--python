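name,icd9_prefix
cardiovascular,410
cardiovascular,411.0
cardiovascular,411.81
cardiovascular,411.89
cardiovascular,411.1
cardiovascular,413
cardiovascular,427.5
cardiovascular,427.1
cardiovascular,427.4
cardiovascular,427.3
cardiovascular,398.91
cardiovascular,428
cardiovascular,414.0
cardiovascular,414.1
cardiovascular,414.8
cardiovascular,414.9
cardiovascular,429.3
cardiovascular,402.9
cardiovascular,430
cardiovascular,431
cardiovascular,432
cardiovascular,433
cardiovascular,434
cardiovascular,435
cardiovascular,436
cardiovascular,437
cardiovascular,427.89
diabetes,250
obesity,278.0
drug_abuse,304
drug_abuse,305
hepatitis_c,070.41
hepatitis_c,070.44
hepatitis_c,070.51
hepatitis_c,070.54
hepatitis_c,070.7
hepatitis_c,V02.62
hiv_aids,042
hiv_aids,043
hiv_aids,044
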