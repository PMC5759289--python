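patient,period,dose_mg_per_day,duration_days,c,note
patient_20,1,30,30,14.02,6 tablets/day for month 1
patient_20,2,25,31,12.07,5 tablets/day for month 2
patient_20,3,20,31,9.6534,4 tablets/day for month 3
patient_20,4,10,89,13.8663,2 tablets/day for months 4-6
patient_20,5,5,182,14.173,1 tablet/day for months 7-12 (first half-year)
patient_20,6,5,182,14.173,1 tablet/day for months 13-18 (second half-year)
patient_31,1,20,30,9.3456,4 tablets/day for month 1
patient_31,2,15,30,7.01,3 tablets/day for month 2
patient_31,3,10,30,4.6726,2 tablets/day for month 3
patient_31,4,5,30,2.3363,1 tablet/day for month 4
patient_31,5,10,30,4.6726,2 tablets/day for month 5
patient_31,6,5,690,53.7345,1 tablet/day for 23 months
patient_55,1,15,30,7.01,3 tablets/day for month 1
patient_55,2,10,30,4.6726,2 tablets/day for month 2
patient_55,3,5,30,2.3363,1 tablet/day for month 3
patient_55,4,5,300,23.3625,1 tablet/day for 10 months
patient_55,5,0,690,0.001,no treatment for 23 months
patient_55,6,20,30,9.3456,second course: 4 tablets/day for 1 month
patient_55,7,15,30,7.01,second course: 3 tablets/day for 1 month
patient_55,8,10,30,4.6726,second course: 2 tablets/day for 1 month
patient_55,9,5,150,11.6817,second course: 1 tablet/day for 5 months
patient_55,10,5,330,25.6996,second course: 1 tablet/day for 11 months
patient_70,1,30,30,14.02,6 tablets/day for month 1
patient_70,2,25,30,11.6817,5 tablets/day for month 2
patient_70,3,20,30,9.3456,4 tablets/day for month 3
patient_70,4,15,30,7.0089,3 tablets/day for month 4
patient_70,5,10,30,4.6726,2 tablets/day for month 5
patient_70,6,5,330,25.6996,1 tablet/day for 11 months
patient_70,7,0,180,0.001,no treatment for 6 months
patient_70,8,20,30,9.3456,second course: 4 tablets/day for 1 month
patient_70,9,10,90,14.02,second course: 2 tablets/day for 3 months
patient_70,10,5,300,23.3625,second course: 1 tablet/day for 10 months
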