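"""CYP3A4 auto-inhibition: why multiple-dose exposure exceeds the
single-dose prediction.

Simulates 200 mg i.v. b.i.d. for 7 days in a normal metabolizer with the
mechanism-based inactivation of CYP3A4 switched on (default) and off, and
reports the steady-state AUC over one 12-h interval plus the fraction of
active hepatic CYP3A4 remaining.
"""

import voripbpk as v

ind = v.generate_individual(30, "male", "NM", v.VariabilitySpec.none(), seed=1)
regimen = v.DosingRegimen.schedule(200, interval_h=12, n_doses=14,
                                   route="iv_infusion", infusion_min=60)
options = v.ModelOptions(rtol=1e-6, atol=1e-8)

for label, tdi in (("inactivation ON ", "default"), ("inactivation OFF", None)):
    model = v.build_model(ind, tdi=tdi, options=options)
    res = model.simulate(regimen, t_end=168, output_dt=0.25)
    auc_tau = v.auc_trapezoid(res.t, res.conc_mg_l, 156, 168)
    e_frac = res.enzyme_liver_cyp3a4[-1] / ind.enzyme_liver_conc["CYP3A4"]
    print(f"{label}: steady-state AUC_tau = {auc_tau:6.1f} mg.h/L, "
          f"active hepatic CYP3A4 = {100 * e_frac:5.1f}% of baseline")

print("\nThe drug inactivates its own secondary clearance pathway; exposure")
print("accumulates beyond what single-dose kinetics would predict.")
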