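patient,age,sex,bmi,disease_duration_years,rf_u_l,acpa_u_l,prednisolone_mg_d,current_cdmard,current_bdmard,previous_cdmard,previous_bdmard,das28_t0,das28_t1,das28_t2,das28_t3,das28_response_t1_printed,das28_response_t2_printed,das28_response_t3_printed,das28_response_best_printed,das28_remission_printed,sdai_t0,sdai_t1,sdai_t2,sdai_t3,sdai_response_t1_printed,sdai_response_t2_printed,sdai_response_t3_printed,sdai_response_best_printed,sdai_remission_printed
RA_01,49,f,32.4,6.9,59.3,184,,,,MTX,,4.06,4.08,4.10,3.17,NR,NR,MR,MR,,11.3,11.8,9.6,7.3,4,-15,-35,,
RA_03,54,f,27.2,0.3,14,0.9,,,,,,4.46,4.02,3.18,2.50,NR,GR,GR,GR,Remission,15.1,12.9,10.0,7.5,-15,-34,-50,MiR,
RA_09,22,f,17.2,21.2,14,0.5,,,,,,5.54,4.63,4.49,3.98,MR,MR,MR,MR,,41.4,41.4,41.1,36.3,0,-1,-12,,
RA_13,61,f,24.0,11.3,49.9,300,,,,MTX,TOC,4.97,5.76,5.68,6.64,NR,NR,NR,NR,,24.3,33.5,27.3,46.0,38,12,89,,
RA_08,65,f,20.0,5.1,935.4,272,2,,,MTX,,4.42,3.92,3.63,3.24,NR,MR,MR,MR,,30.8,21.7,22.9,19.4,-30,-26,-37,,
RA_16,41,f,25.4,0.9,14,0.4,2.5,,,,,2.32,2.18,2.47,2.18,SR,SR,SR,SR,Remission,6.3,4.6,5.7,4.9,-27,-10,-22,,
RA_12,31,f,22.7,7.3,70.6,212,5,,,,,3.13,2.75,1.99,2.48,NR,MR,MR,MR,Remission,13.0,7.4,6.0,6.3,-43,-54,-52,MiR,
RA_18,65,f,20.5,4.6,14,340,5,,,,,4.98,4.47,3.98,3.17,NR,MR,GR,GR,,26.3,22.2,18.1,14.8,-16,-31,-44,,
RA_19,70,f,25.1,6.6,14,0.4,5,,,MTX,,5.96,5.37,4.64,4.37,NR,MR,MR,MR,,33.5,23.5,21.3,19.7,-30,-36,-41,,
RA_05,77,m,20.6,36.1,31.3,67,,MTX,,,,5.04,3.23,2.66,2.58,MR,GR,GR,GR,Remission,19.5,8.8,12.2,5.6,-55,-37,-71,MoR,
RA_04,50,f,21.5,1.7,31.3,340,5,MTX,,,,1.82,1.25,1.05,0.49,SR,MR,GR,GR,Remission,3.6,2.8,2.7,0.1,-22,-25,-97,MaR,Remission
RA_17,52,f,20.8,8.6,104,285,5,LEF,,MTX,,4.78,4.70,3.21,3.75,NR,MR,MR,MR,,24.7,23.6,18.1,17.6,-4,-27,-29,,
RA_11,72,f,27.8,16.1,195.1,275,6,MTX,,,,5.20,5.03,4.45,3.96,NR,MR,MR,MR,,28.4,20.8,14.0,10.5,-27,-51,-63,MiR,
RA_02,63,f,32.9,14.9,14,0.4,10,MTX,,,ABT;RTX,7.05,6.26,6.70,6.18,NR,NR,NR,NR,,49.9,36.8,44.9,41.2,-26,-10,-17,,
RA_10,53,f,25.5,35.2,600,12.4,,,TOC,MTX;SSZ;HCQ,ADA;ETN,2.64,1.93,1.41,1.55,MR,GR,MR,GR,Remission,11.1,7.6,3.2,2.6,-32,-71,-77,MoR,Remission
RA_07,52,f,39.9,0.9,151,60,5,,ETN,MTX,,5.83,4.57,4.31,2.93,MR,MR,GR,GR,,38.3,24.4,21.2,7.1,-36,-45,-81,MoR,
RA_14,34,f,23.9,20.3,119.7,30,15,,CZP,,,3.97,5.16,3.89,3.61,NR,NR,NR,NR,,19.3,27.6,19.4,16.3,43,1,-16,,
RA_20,61,f,26.1,25.6,14,0.8,5,MTX,ABT,,,4.93,5.06,4.26,3.49,NR,MR,MR,MR,,24.7,25.1,15.4,14.5,2,-38,-41,,
RA_06,22,f,25.5,6.1,240.4,2.6,7.5,MTX,ADA,LEF,CZP;TOC,3.24,2.62,1.93,1.96,MR,GR,GR,GR,Remission,11.4,6.0,5.5,1.7,-47,-52,-85,MaR,Remission
RA_15,30,f,22.3,1.9,14,136,10,MTX,ETN,,ADA;ABT,3.45,3.17,2.51,2.23,NR,MR,GR,GR,Remission,13.6,11.1,6.1,6.0,-18,-55,-56,MiR,
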