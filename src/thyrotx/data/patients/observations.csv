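patient,day,analyte,value,note
patient_20,0,FT4,25.63,first clinical visit
patient_20,92,FT4,17.7,month-3 follow-up
patient_20,181,FT4,13.8,month-6 follow-up
patient_20,365,FT4,13.14,month-12 follow-up
patient_20,547,FT4,12.46,month-18 follow-up; treatment stopped
patient_20,0,TRAb,7.5,first clinical visit
patient_20,365,TRAb,0.7,month-12 follow-up
patient_20,547,TRAb,0.6,month-18 follow-up; treatment stopped
patient_31,0,FT4,26.43,first clinical visit
patient_31,120,FT4,20.0,month-4 follow-up
patient_31,840,FT4,11.5,end of treatment; a normal visit 2 years later (FT4 11.36) is out of course
patient_31,0,TRAb,1.74,first clinical visit
patient_31,840,TRAb,0.45,end of treatment; a normal visit 2 years later (TRAb 0.43) is out of course
patient_55,0,FT4,27.01,first clinical visit
patient_55,90,FT4,10.03,month-3 follow-up
patient_55,270,FT4,8.99,month-9 follow-up; treatment stopped
patient_55,1080,FT4,40.28,relapse visit after 23 months off treatment
patient_55,1170,FT4,12.41,second course month-3 follow-up
patient_55,1320,FT4,10.79,second course month-8 follow-up
patient_55,1650,FT4,11.36,second course final visit
patient_55,0,TRAb,6.2,first clinical visit
patient_55,270,TRAb,1.17,month-9 follow-up; treatment stopped
patient_55,1080,TRAb,2.46,relapse visit after 23 months off treatment
patient_55,1650,TRAb,0.7,second course final visit
patient_70,0,FT4,35.04,first clinical visit
patient_70,300,FT4,9.3,month-10 follow-up
patient_70,480,FT4,8.97,end of first course; treatment stopped
patient_70,660,FT4,31.2,relapse visit after 6 months off treatment
patient_70,870,FT4,9.87,second course month-7 follow-up
patient_70,1050,FT4,9.87,second course month-13 follow-up; treatment stopped
patient_70,0,TRAb,8.8,first clinical visit
patient_70,300,TRAb,1.3,month-10 follow-up
patient_70,480,TRAb,1.4,end of first course; treatment stopped
patient_70,660,TRAb,4.7,relapse visit after 6 months off treatment
patient_70,870,TRAb,0.9,second course month-7 follow-up
patient_70,1050,TRAb,0.3,second course month-13 follow-up; treatment stopped
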