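patient_id,birth_date,sex,race,region,state
P01,1980-05-10,male,white,urban,MO
P02,1988-06-15,female,black,suburban,NJ
P03,1975-01-01,male,white,rural,IA
P04,1970-02-02,female,other,urban,KS
P05,1985-03-03,male,white,urban,MO
P06,1993-06-01,female,black,rural,MS
P07,1982-04-04,male,white,urban,MO
P08,1978-05-05,female,white,suburban,NJ
P09,1986-01-20,male,black,urban,MO
P10,1965-07-07,female,white,rural,IA
P11,1990-08-08,male,white,urban,MO
P12,1984-06-02,female,black,suburban,NJ
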