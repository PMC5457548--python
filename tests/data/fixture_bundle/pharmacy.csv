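patient_id,dispense_date,agent_code,agent_class,days_supply,paid_amount,branded,service_year
P01,2010-01-01,PP1M,PP1M,30,800.00,True,2010
P01,2010-02-01,PP1M,PP1M,30,800.00,True,2010
P01,2010-03-03,PP1M,PP1M,30,800.00,True,2010
P01,2010-04-02,PP1M,PP1M,30,800.00,True,2010
P01,2010-05-02,PP1M,PP1M,30,800.00,True,2010
P01,2010-06-01,PP1M,PP1M,30,800.00,True,2010
P02,2010-03-01,OAA_RISP,risperidone,30,120.00,False,2010
P02,2010-03-31,OAA_RISP,risperidone,30,120.00,False,2010
P02,2010-04-30,OAA_RISP,risperidone,30,120.00,False,2010
P02,2010-05-30,OAA_RISP,risperidone,30,120.00,False,2010
P03,2010-01-01,OAA_RISP,risperidone,30,120.00,False,2010
P03,2010-05-01,OAA_RISP,risperidone,30,120.00,False,2010
P04,2009-10-01,PP1M,PP1M,30,780.00,True,2009
P04,2010-03-01,PP1M,PP1M,30,800.00,True,2010
P04,2010-03-20,PP1M,PP1M,30,800.00,True,2010
P05,2010-01-01,OAA_OLAN,olanzapine,30,95.00,False,2010
P05,2010-01-25,OAA_OLAN,olanzapine,30,95.00,False,2010
P05,2010-02-25,OAA_OLAN,olanzapine,30,95.00,False,2010
P06,2010-05-01,OAA_RISP,risperidone,30,120.00,False,2010
P06,2010-05-25,OAA_RISP,risperidone,30,120.00,False,2010
P07,2010-04-01,OAA_RISP,risperidone,30,120.00,False,2010
P07,2010-04-20,OAA_RISP,risperidone,30,120.00,False,2010
P08,2010-01-15,OAA_OLAN,olanzapine,30,95.00,False,2010
P08,2010-02-10,OAA_OLAN,olanzapine,30,95.00,False,2010
P09,2010-02-01,OAA_OLAN,olanzapine,30,95.00,False,2010
P09,2010-04-02,OAA_OLAN,olanzapine,30,95.00,False,2010
P09,2010-06-01,OAA_OLAN,olanzapine,30,95.00,False,2010
P09,2010-07-31,OAA_OLAN,olanzapine,30,95.00,False,2010
P09,2010-09-29,OAA_OLAN,olanzapine,30,95.00,False,2010
P09,2010-11-28,OAA_OLAN,olanzapine,30,95.00,False,2010
P11,2010-01-01,ANX_001,anxiolytic,30,25.00,False,2010
P11,2010-02-01,ANX_001,anxiolytic,30,25.00,False,2010
P12,2010-06-01,OAA_RISP,risperidone,30,120.00,False,2010
P12,2010-06-01,OAA_RISP,risperidone,30,120.00,False,2010
P12,2010-07-01,OAA_RISP,risperidone,30,120.00,False,2010
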