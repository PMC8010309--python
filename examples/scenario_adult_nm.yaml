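# Scenario config for `voripbpk simulate`: 20 CYP2C19-normal adult males,
# single 200 mg i.v. dose infused over 60 min, followed for 48 h.
population:
  n: 20
  age_range: [20, 40]
  male_fraction: 1.0
  phenotype_mix: {NM: 1.0}
  seed: 1
regimen:
  route: iv_infusion
  dose: 200
  unit: mg
  infusion_min: 60
  n_doses: 1
t_end_h: 48
output_dt_h: 0.25
rtol: 1.0e-6
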