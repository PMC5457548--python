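patient_id,start_date,end_date,service_category,dx_codes,paid_amount,agent_code,branded,service_year
P01,2009-06-01,2009-06-01,outpatient,295.30,50.00,,False,2009
P01,2009-12-15,2009-12-15,outpatient,295.30,50.00,,False,2009
P01,2009-07-01,2009-07-03,mhi_admission,295.30,2000.00,,False,2009
P01,2010-05-10,2010-05-14,inpatient,295.30,5000.00,,False,2010
P02,2009-10-01,2009-10-01,outpatient,295.30,50.00,,False,2009
P02,2010-06-01,2010-06-01,outpatient,295.30;300.00,50.00,,False,2010
P03,2009-11-01,2009-11-01,outpatient,295.30,50.00,,False,2009
P03,2010-02-01,2010-02-01,outpatient,295.30,50.00,,False,2010
P04,2009-09-15,2009-09-15,outpatient,295.30,50.00,,False,2009
P04,2010-01-10,2010-01-10,outpatient,295.30,50.00,,False,2010
P05,2010-01-05,2010-01-05,outpatient,295.30,50.00,,False,2010
P05,2010-02-05,2010-02-05,outpatient,296.30,50.00,,False,2010
P06,2010-01-01,2010-01-01,outpatient,295.30,50.00,,False,2010
P06,2010-03-01,2010-03-01,outpatient,295.30,50.00,,False,2010
P07,2010-04-05,2010-04-05,outpatient,295.30,50.00,,False,2010
P07,2010-06-01,2010-06-01,outpatient,295.30,50.00,,False,2010
P08,2009-09-01,2009-09-01,outpatient,295.30,50.00,,False,2009
P08,2010-02-01,2010-02-01,outpatient,295.30,50.00,,False,2010
P09,2009-12-01,2009-12-01,outpatient,295.30,50.00,,False,2009
P09,2010-03-01,2010-03-01,outpatient,295.30;311,50.00,,False,2010
P10,2009-08-01,2009-08-01,outpatient,295.30,50.00,,False,2009
P10,2010-04-01,2010-04-01,outpatient,295.30,50.00,,False,2010
P10,2010-02-01,2010-02-01,outpatient,,900.00,PP1M,True,2010
P10,2010-03-01,2010-03-01,outpatient,,900.00,PP1M,True,2010
P11,2010-01-05,2010-01-05,outpatient,295.30,50.00,,False,2010
P11,2010-02-05,2010-02-05,outpatient,295.30,50.00,,False,2010
P12,2010-03-01,2010-03-01,outpatient,295.30,50.00,,False,2010
P12,2010-07-15,2010-07-15,outpatient,295.30;250.00,50.00,,False,2010
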