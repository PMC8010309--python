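parameter,unit,value
molecular_weight,g/mol,349.3
fu_plasma,fraction,0.42
logp,,1.65
pka_base,,1.76
solubility_mg_ml,mg/mL,3.2
solubility_ph,,1.0
intestinal_permeability_cm_s,cm/s,2.81e-05
gfr_fraction,,1
cyp2c19_km_umol_l,umol/L,3.5
cyp2c19_kcat_per_min,1/min,1.19
cyp3a4_km_umol_l,umol/L,11
cyp3a4_kcat_per_min,1/min,2.3
cyp2c9_km_umol_l,umol/L,20
cyp2c9_kcat_per_min,1/min,0.0556
cyp3a4_kinact_per_min,1/min,0.04
cyp3a4_ki_umol_l,umol/L,9.33
dt50_tablet_min,min,30
weibull_shape_tablet,,1.29
cyp2c19_ref_nm_umol_l,umol/L,0.76
cyp3a4_ref_umol_l,umol/L,4.32
cyp2c9_ref_umol_l,umol/L,3.84
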