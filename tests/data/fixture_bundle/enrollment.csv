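patient_id,start_date,end_date,capitated,dual_coverage
P01,2008-01-01,2012-12-31,False,False
P02,2008-01-01,2012-12-31,True,False
P03,2008-01-01,2012-12-31,False,False
P04,2008-01-01,2012-12-31,False,True
P05,2008-01-01,2012-12-31,False,False
P06,2008-01-01,2012-12-31,False,False
P07,2009-12-01,2012-12-31,False,False
P08,2008-06-01,2010-09-30,False,False
P09,2008-01-01,2012-12-31,True,True
P10,2008-01-01,2012-12-31,False,False
P11,2008-01-01,2012-12-31,False,False
P12,2008-01-01,2012-12-31,False,False
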