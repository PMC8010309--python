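"""Single 200 mg i.v. dose (60-min infusion) across CYP2C19 phenotypes.

Builds one reference 30-year-old male per phenotype (no inter-individual
variability), simulates the whole-body model, and reports NCA exposure.
The spread across phenotypes — poor metabolizers roughly 2-3x above normal
metabolizers — is the pharmacogenetic signal the model encodes through the
hepatic CYP2C19 abundance (0.76 umol/L for NM, 0 for PM).
"""

import voripbpk as v

regimen = v.DosingRegimen.single_iv(200, infusion_min=60)
options = v.ModelOptions(rtol=1e-6, atol=1e-8)

print("phenotype  AUC_inf (mg.h/L)  Cmax (mg/L)")
for phenotype in ("RM", "NM", "IM", "PM"):
    ind = v.generate_individual(30, "male", phenotype,
                                v.VariabilitySpec.none(), seed=1)
    model = v.build_model(ind, options=options)
    res = model.simulate(regimen, t_end=48, output_dt=0.25)
    auc = v.auc_inf(res.t, res.conc_mg_l, window=(12, 24))
    print(f"{phenotype:>9}  {auc:16.2f}  {res.conc_mg_l.max():11.2f}")

print("\nAUC rises as functional CYP2C19 falls; Cmax barely moves because")
print("the 1-h infusion peak is set by distribution, not elimination.")
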