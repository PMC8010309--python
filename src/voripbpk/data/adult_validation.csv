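phenotype,dose_mg,schedule,route,infusion_min,male_pct,age,parameter,predicted,observed,ratio,t_last_h,reference
RM,50,sig,iv_infusion,120,63,30,AUC_obs,1.28,1.02,1.25,24,B10
RM,50,sig,iv_infusion,120,63,30,Cmax,0.38,0.320,1.19,24,B10
RM,50,sig,oral_tablet,,63,30,AUC_obs,0.76,0.40,1.9,24,B10
RM,50,sig,oral_tablet,,63,30,Cmax,0.22,0.167,1.32,24,B10
RM,200,sig,oral_tablet,,100,21,AUC_obs,5.45,3.39,1.61,24,B43
RM,200,sig,oral_tablet,,100,21,Cmax,1.32,1.15,1.15,24,B43
RM,400,sig,iv_infusion,120,71,30,AUC_obs,15.8,16.5,0.96,24,B10
RM,400,sig,iv_infusion,120,71,30,Cmax,3.50,3.29,1.06,24,B10
RM,400,sig,iv_infusion,120,67,25,AUC_obs,17.4,18.8,0.93,24,B35
RM,400,sig,iv_infusion,120,67,25,Cmax,3.72,4.05,0.92,24,B35
RM,400,sig,oral_tablet,,71,30,AUC_obs,13.0,15.3,0.85,24,B10
RM,400,sig,oral_tablet,,71,30,Cmax,2.56,3.21,0.90,24,B10
RM,400,sig,oral_tablet,,67,25,AUC_obs,14.6,13.6,1.07,24,B35
RM,400,sig,oral_tablet,,67,25,Cmax,2.79,2.90,0.96,24,B35
RM,400,sig,oral_capsule,,0,29,AUC_obs,13.9,15.9,0.87,24,B23
RM,400,sig,oral_capsule,,0,29,Cmax,2.81,2.97,0.95,24,B23
RM,400,sig,oral_capsule,,100,27,AUC_inf,11.3,13.3,0.85,,B46
RM,400,sig,oral_capsule,,100,27,Cmax,2.42,2.16,1.12,,B46
NM,50,sig,iv_infusion,120,100,35,AUC_obs,1.42,1.24,1.15,24,B10
NM,50,sig,iv_infusion,120,100,35,Cmax,0.38,0.345,1.10,24,B10
NM,50,sig,oral_tablet,,100,35,AUC_obs,0.84,0.53,1.58,24,B10
NM,50,sig,oral_tablet,,100,35,Cmax,0.23,0.167,1.38,24,B10
NM,200,sig,iv_infusion,60,100,26.7,AUC_inf,8.33,6.51,1.28,,B15
NM,200,sig,iv_infusion,60,100,26.7,Cmax,2.76,2.74,1.01,,B15
NM,200,sig,oral_tablet,,100,22,AUC_obs,7.35,5.16,1.42,24,B16
NM,200,sig,oral_tablet,,100,22,Cmax,1.53,1.45,1.06,24,B16
NM,200,sig,oral_tablet,,100,21,AUC_obs,7.41,6.18,1.20,24,B43
NM,200,sig,oral_tablet,,100,21,Cmax,1.47,1.65,0.89,24,B43
NM,200,"qd,d1",oral_generic,,100,26.7,AUC_tau,6.74,4.64,1.45,24,B15
NM,200,"qd,d1",oral_generic,,100,26.7,Cmax,1.36,2.32,0.59,24,B15
NM,200,"bid,d2-7",oral_generic,,100,26.7,AUC_tau,19.0,19.3,0.98,12,B15
NM,200,"bid,d2-7",oral_generic,,100,26.7,Cmax,2.94,3.21,0.92,12,B15
NM,200,"bid,d2-2.5 (400 bid d1)",oral_generic,,83,27,AUC_tau,15.5,12.9,1.20,12,B51
NM,200,"bid,d2-2.5 (400 bid d1)",oral_generic,,83,27,Cmax,2.49,3.01,0.83,12,B51
NM,200,"bid,d2-3.5 (400 bid d1)",oral_generic,,100,29,AUC_12,16.8,31.0,0.54,12,B5
NM,200,"bid,d2-3.5 (400 bid d1)",oral_generic,,100,29,Cmax,2.79,4.02,0.69,12,B5
NM,400,sig,iv_infusion,120,100,35,AUC_obs,18.3,21.4,0.86,24,B10
NM,400,sig,iv_infusion,120,100,35,Cmax,3.57,3.61,0.99,24,B10
NM,400,sig,iv_infusion,120,50,31,AUC_obs,19.59,18.8,1.04,24,B35
NM,400,sig,iv_infusion,120,50,31,Cmax,3.60,4.05,0.89,24,B35
NM,400,sig,oral_tablet,,100,35,AUC_obs,15.6,13.6,1.15,24,B10
NM,400,sig,oral_tablet,,100,35,Cmax,2.67,2.21,1.21,24,B10
NM,400,sig,oral_tablet,,50,31,AUC_obs,16.9,13.6,1.24,24,B35
NM,400,sig,oral_tablet,,50,31,Cmax,2.68,2.90,0.92,24,B35
NM,400,sig,oral_capsule,,100,28,AUC_obs,16.6,15.9,1.04,24,B23
NM,400,sig,oral_capsule,,100,28,Cmax,2.63,2.97,0.89,24,B23
NM,400,sig,oral_capsule,,100,27,AUC_inf,16.8,16.4,1.02,,B46
NM,400,sig,oral_capsule,,100,27,Cmax,2.85,3.10,0.92,,B46
IM,50,sig,iv_infusion,120,75,30,AUC_obs,1.61,1.13,1.42,24,B10
IM,50,sig,iv_infusion,120,75,30,Cmax,0.43,0.32,1.34,24,B10
IM,50,sig,oral_tablet,,75,30,AUC_obs,1.04,0.58,1.79,24,B10
IM,50,sig,oral_tablet,,75,30,Cmax,0.27,0.22,1.23,24,B10
IM,200,sig,iv_infusion,60,100,24.7,AUC_inf,11.6,10.1,1.15,,B15
IM,200,sig,iv_infusion,60,100,24.7,Cmax,3.03,3.36,0.90,,B15
IM,200,"qd,d1",oral_generic,,100,24.7,AUC_tau,9.90,7.02,1.41,24,B15
IM,200,"qd,d1",oral_generic,,100,24.7,Cmax,1.55,1.81,0.86,24,B15
IM,200,"bid,d2-7",oral_generic,,100,24.7,AUC_tau,37.7,42.4,0.89,12,B15
IM,200,"bid,d2-7",oral_generic,,100,24.7,Cmax,4.60,5.78,0.80,12,B15
IM,400,sig,iv_infusion,120,63,26,AUC_obs,31.3,37.4,0.84,24,B35
IM,400,sig,iv_infusion,120,63,26,Cmax,3.96,4.33,0.91,24,B35
IM,400,sig,iv_infusion,120,75,30,AUC_obs,25.8,25.0,1.03,24,B10
IM,400,sig,iv_infusion,120,75,30,Cmax,4.11,3.82,1.08,24,B10
IM,400,sig,oral_tablet,,75,30,AUC_obs,23.5,23.2,1.01,24,B10
IM,400,sig,oral_tablet,,75,30,Cmax,3.12,3.32,0.94,24,B10
IM,400,sig,oral_tablet,,63,26,AUC_obs,29.0,30.9,0.94,24,B35
IM,400,sig,oral_tablet,,63,26,Cmax,3.00,3.28,0.91,24,B35
IM,400,sig,oral_capsule,,78,26,AUC_obs,27.5,20.7,1.33,24,B23
IM,400,sig,oral_capsule,,78,26,Cmax,3.12,2.85,1.09,24,B23
IM,400,sig,oral_capsule,,100,26,AUC_inf,27.6,25.7,1.07,,B46
IM,400,sig,oral_capsule,,100,26,Cmax,3.17,2.84,1.12,,B46
PM,50,"bid,d2-2.5 (100 bid d1)",oral_generic,,100,29,AUC_tau,6.32,6.00,1.05,12,B51
PM,50,"bid,d2-2.5 (100 bid d1)",oral_generic,,100,29,Cmax,0.85,0.76,1.12,12,B51
PM,200,sig,iv_infusion,60,100,27.3,AUC_inf,20.8,20.5,1.01,,B15
PM,200,sig,iv_infusion,60,100,27.3,Cmax,3.10,2.92,1.06,,B15
PM,200,sig,oral_tablet,,100,21.6,AUC_obs,13.9,17.2,0.81,24,B16
PM,200,sig,oral_tablet,,100,21.6,Cmax,1.77,1.36,1.30,24,B16
PM,200,sig,oral_tablet,,100,21,AUC_obs,14.6,16.3,0.90,24,B43
PM,200,sig,oral_tablet,,100,21,Cmax,1.70,1.89,0.90,24,B43
PM,200,"qd,d1",oral_generic,,100,27.3,AUC_tau,11.8,9.25,1.28,24,B15
PM,200,"qd,d1",oral_generic,,100,27.3,Cmax,1.54,2.41,0.64,24,B15
PM,200,"bid,d2-7",oral_generic,,100,27.3,AUC_tau,59.8,58.7,1.02,12,B15
PM,200,"bid,d2-7",oral_generic,,100,27.3,Cmax,6.42,7.21,0.89,12,B15
PM,200,"bid,d2-3.5 (400 bid d1)",oral_generic,,100,29,AUC_12,67.4,77.1,0.87,12,B5
PM,200,"bid,d2-3.5 (400 bid d1)",oral_generic,,100,29,Cmax,7.14,10.9,0.66,12,B5
PM,400,sig,iv_infusion,120,50,30,AUC_obs,48.9,44.4,1.10,24,B35
PM,400,sig,iv_infusion,120,50,30,Cmax,4.27,4.30,0.99,24,B35
PM,400,sig,oral_tablet,,50,30,AUC_obs,47.0,41.6,1.13,24,B35
PM,400,sig,oral_tablet,,50,30,Cmax,3.35,3.91,0.86,24,B35
PM,400,sig,oral_capsule,,33,29,AUC_obs,49.4,42.4,1.17,24,B23
PM,400,sig,oral_capsule,,33,29,Cmax,3.74,3.24,1.15,24,B23
PM,400,sig,oral_capsule,,100,31,AUC_inf,41.6,45.7,0.91,,B35
PM,400,sig,oral_capsule,,100,31,Cmax,3.19,3.13,1.02,,B35
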