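"""Pediatric vs adult clearance at matched mg/kg dosing.

Children clear voriconazole 2-3x faster per kg than adults: their livers are
a larger fraction of body mass, blood flows per kg are higher, and the
in-vivo ontogeny of CYP2C19/3A4/2C9 peaks above the adult level during
childhood.  Small cohorts (n=25) keep this example quick.
"""

import numpy as np

import voripbpk as v

options = v.ModelOptions(rtol=1e-6, atol=1e-8)
regimen = v.DosingRegimen.single_iv(4, infusion_min=60, per_kg=True)


def mean_cl_per_kg(age_range, seed):
    spec = v.PopulationSpec(n=25, age_range=age_range, male_fraction=0.5,
                            phenotype_mix={"NM": 1.0}, seed=seed)
    pop = v.generate_population(spec)
    res = v.simulate_population(pop, regimen, t_end=48, options=options,
                                output_dt=0.25)
    return float(np.mean([
        r.dose_total_mg / v.auc_inf(r.t, r.conc_mg_l, window=(12, 24))
        / r.body_weight for r in res]))


child = mean_cl_per_kg((2, 12), seed=1)
adult = mean_cl_per_kg((20, 40), seed=2)
print(f"NM children 2-12 y: CL = {child:.3f} L/h/kg")
print(f"NM adults  20-40 y: CL = {adult:.3f} L/h/kg")
print(f"ratio = {child / adult:.2f}  (expected in the 2-3x range)")
print("\nAt equal mg/kg doses children are systematically under-exposed,")
print("which is why label doses per kg are higher in children.")
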