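item,unit_cost,price_year,source
device,15,2011,manufacturer
ward_day,311,2011,NHS Reference Costs 2010/2011
itu_day,1515,2008,NHS Reference Costs 2007/2008
hdu_day,856,2008,NHS Reference Costs 2007/2008
gp_visit,36,2011,PSSRU Unit Costs 2010-2011
practice_nurse_visit,13,2011,PSSRU Unit Costs 2010-2011
district_nurse_visit,73,2011,PSSRU Unit Costs 2010-2011
outpatient_visit,101,2011,NHS Reference Costs 2010/2011
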