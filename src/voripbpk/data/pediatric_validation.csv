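phenotype_mix,dose_mg_kg,schedule,route,infusion_min,male_pct,age_mean,age_lo,age_hi,parameter,predicted,observed,ratio,reference
NM:0.58;IM:0.42,6,"bid,d1 (4 bid d2-4)",iv_infusion,120,75,3.7,2,6,AUC_tau,11.49,11.77,0.98,B41
NM:0.58;IM:0.42,6,"bid,d1 (4 bid d2-4)",iv_infusion,120,75,3.7,2,6,Cmax,3.33,3.35,0.99,B41
NM:0.58;IM:0.42,6,"bid,d5-8",iv_infusion,120,75,3.7,2,6,AUC_tau,20.82,21.93,0.95,B41
NM:0.58;IM:0.42,6,"bid,d5-8",iv_infusion,120,75,3.7,2,6,Cmax,3.92,4.69,0.83,B41
NM:0.73;IM:0.27,6,"bid,d1 (4 bid d2-4)",iv_infusion,120,75,8.7,6,12,AUC_tau,19.78,11.95,1.66,B41
NM:0.73;IM:0.27,6,"bid,d1 (4 bid d2-4)",iv_infusion,120,75,8.7,6,12,Cmax,4.06,3.07,1.32,B41
NM:0.73;IM:0.27,6,"bid,d5-8",iv_infusion,120,75,8.7,6,12,AUC_tau,36.83,24.05,1.53,B41
NM:0.73;IM:0.27,6,"bid,d5-8",iv_infusion,120,75,8.7,6,12,Cmax,6.19,4.01,1.54,B41
NM:0.75;IM:0.17;PM:0.08,6,"bid,d1-4",iv_infusion,120,45.8,2.8,2,6,AUC_tau,22.39,18.22,1.23,B41
NM:0.75;IM:0.17;PM:0.08,6,"bid,d1-4",iv_infusion,120,45.8,2.8,2,6,Cmax,4.85,4.61,1.05,B41
NM:0.75;IM:0.17;PM:0.08,8,"bid,d5-8",iv_infusion,160,45.8,2.8,2,6,AUC_tau,33.84,25.57,1.32,B41
NM:0.75;IM:0.17;PM:0.08,8,"bid,d5-8",iv_infusion,160,45.8,2.8,2,6,Cmax,6.00,4.80,1.25,B41
NM:1.0,6,"bid,d1-4",iv_infusion,120,45.8,8.1,6,12,AUC_tau,26.57,16.23,1.64,B41
NM:1.0,6,"bid,d1-4",iv_infusion,120,45.8,8.1,6,12,Cmax,5.25,3.99,1.32,B41
NM:1.0,8,"bid,d5-8",iv_infusion,160,45.8,8.1,6,12,AUC_tau,41.30,34.68,1.19,B41
NM:1.0,8,"bid,d5-8",iv_infusion,160,45.8,8.1,6,12,Cmax,6.65,6.92,0.96,B41
NM:1.0,8,"bid,d2-7 (9 bid d1)",iv_infusion,160,42.9,9.2,3,14,AUC_tau,28.87,36.0,0.80,B24
NM:1.0,8,"bid,d2-7 (9 bid d1)",iv_infusion,160,42.9,9.2,3,14,Cmax,5.42,5.32,1.02,B24
IM:1.0,8,"bid,d2-7 (9 bid d1)",iv_infusion,160,42.9,9.2,3,14,AUC_tau,58.09,56.4,1.13,B24
IM:1.0,8,"bid,d2-7 (9 bid d1)",iv_infusion,160,42.9,9.2,3,14,Cmax,8.01,8.12,0.99,B24
PM:1.0,8,"bid,d2-7 (9 bid d1)",iv_infusion,160,42.9,9.2,3,14,AUC_tau,115,128,0.90,B24
PM:1.0,8,"bid,d2-7 (9 bid d1)",iv_infusion,160,42.9,9.2,3,14,Cmax,12.78,15.70,0.81,B24
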