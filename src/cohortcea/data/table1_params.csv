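name,family,mean,se,unit,group,source
sbp_int_m,normal,147,1.102,mmHg,effectiveness,RCT
sbp_int_f,normal,141,1.042,mmHg,effectiveness,RCT
smoke_int_m,beta,0.228,0.023,proportion,effectiveness,RCT
smoke_int_f,beta,0.006,0.001,proportion,effectiveness,RCT
sbp_com_m,normal,154,1.673,mmHg,effectiveness,RCT
sbp_com_f,normal,159,1.558,mmHg,effectiveness,RCT
smoke_com_m,beta,0.145,0.015,proportion,effectiveness,RCT
smoke_com_f,fixed,0,0,proportion,effectiveness,RCT
mort_cvd_m,beta,0.003,0.001,per year,mortality,Minh et al. 2006
mort_cvd_f,beta,0.002,0.000,per year,mortality,Minh et al. 2006
c_int_design,gamma,335294,67059,VND per person-year,cost,RCT
c_int_implement,gamma,426471,85294,VND per person-year,cost,RCT
c_int_monitor,gamma,3238235,647647,VND per person-year,cost,RCT
c_acute_central,gamma,51652576,9879613,VND per admission,cost,Hospital database
c_acute_prov,gamma,9623739,448833,VND per admission,cost,Hospital database
c_acute_dist,gamma,1725492,113419,VND per admission,cost,Hospital database
c_stable_central,gamma,785000,343566,VND per visit,cost,Hospital database
c_stable_prov,gamma,562580,2679,VND per visit,cost,Hospital database
c_htn_prov,gamma,475225,4601,VND per visit,cost,Hospital database
c_htn_dist,gamma,316417,1906,VND per visit,cost,Hospital database
c_travel_inpt,gamma,1047979,225224,VND per admission,cost,Patient interview
c_travel_outpt,gamma,46477,11653,VND per visit,cost,Patient interview
c_meals_inpt,gamma,635947,44933,VND per admission,cost,Patient interview
c_meals_outpt,gamma,6898,1220,VND per visit,cost,Patient interview
c_other_inpt,gamma,454905,108018,VND per admission,cost,Patient interview
c_other_outpt,gamma,75880,15638,VND per visit,cost,Patient interview
f_inpt_cent,normal,1.39,0.05,per year,frequency,Patient interview
f_inpt_prov,normal,1.36,0.19,per year,frequency,Patient interview
f_inpt_dist,normal,0.39,0.05,per year,frequency,Patient interview
f_outpt_cent,normal,1.70,0.29,per year,frequency,Patient interview
f_outpt_prov,normal,5.86,0.39,per year,frequency,Patient interview
f_outpt_dist,normal,7.50,0.36,per year,frequency,Patient interview
u_htn_m,beta,0.84,0.05,utility,utility,Patient interview
u_htn_f,beta,0.64,0.04,utility,utility,Patient interview
u_stable_m,beta,0.73,0.06,utility,utility,Patient interview
u_stable_f,beta,0.64,0.06,utility,utility,Patient interview
u_acute_m,beta,0.43,0.08,utility,utility,Patient interview
u_acute_f,beta,0.47,0.07,utility,utility,Patient interview
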