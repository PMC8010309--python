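# Methods

`voripbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model of voriconazole for adults and children, together with the
downstream PK/PD machinery (probability of target attainment, cumulative
fraction of response) used to choose pediatric intravenous doses.

## Model structure

The body is represented by fourteen perfusion-limited organ compartments
(lung, brain, heart, kidney, liver, spleen, gut wall, stomach, pancreas,
muscle, adipose, skin, bone, gonads) plus arterial and venous blood.  The
lung is in series with the heart and carries the whole cardiac output; all
other organs are perfused in parallel from arterial blood.  Gut wall,
stomach, pancreas and spleen drain through the portal vein into the liver,
which also receives the hepatic artery.  For organ *i* with volume `V_i`,
flow `Q_i` and tissue:plasma partition coefficient `Kp_i`,

    dA_i/dt = Q_i (C_art - A_i / (V_i Kp_i))

Blood and plasma concentrations are treated as equal (the blood:plasma
ratio of voriconazole is close to 1); all amounts are carried in µmol,
concentrations in µmol/L, time in hours, with conversion to mg/L via the
molecular weight (349.3 g/mol) only at the reporting boundary.

**Partition coefficients** follow Poulin–Theil: each tissue is a mixture of
water, neutral lipid and phospholipid (packaged composition table, one row
per organ plus plasma), with the octanol:water partition coefficient
(logP 1.65) weighting the lipid phase, the vegetable-oil variant
(log D = 1.115·logP − 1.35) for adipose, and a tissue unbound fraction
conventionally set to half the plasma binding strength (fu = 0.42).  For
this moderately lipophilic neutral base the resulting steady-state volume
is ≈1.1 L/kg; the method is known to underestimate the reported in-vivo
Vss of voriconazole (~4.6 L/kg), which affects the shape of the early
distribution phase but not clearance-driven exposure (AUC), the quantity
the model is verified on.

**Metabolism.**  CYP2C19, CYP3A4 and CYP2C9 (liver; CYP3A4 also in gut
wall) clear the drug by Michaelis–Menten kinetics on the unbound
liver-water concentration `Cu = fu · C_liver / Kp_liver`:

    rate = kcat · E · V_liver · Cu / (Km + Cu)

with Km = 3.5 / 11 / 20 µmol/L and kcat = 1.19 / 2.3 / 0.0556 min⁻¹ for
CYP2C19 / CYP3A4 / CYP2C9.  Hepatic enzyme concentrations are
0.76 / 4.32 / 3.84 µmol/L in a CYP2C19-normal adult.  CYP2C19 abundance is
phenotype-specific: UM 1.41, RM 1.36, NM 0.76, IM-with-\*17 0.63,
IM (diplotype unresolved) 0.46, IM-with-\*1 0.29, PM 0 µmol/L.  Gut-wall
CYP3A4 defaults to 1% of the hepatic molar content (configurable),
capturing a modest first-pass component.

**Auto-inhibition (TDI).**  Active CYP3A4 is a dynamic state obeying

    dE/dt = kdeg·E0 − (kdeg + kinact·I/(KI + I))·E

with kinact = 0.04 min⁻¹, KI = 9.33 µmol/L, and kdeg defaulting to
3.2·10⁻⁴ min⁻¹ (≈36 h turnover half-life, the conventional hepatic CYP3A4
value; configurable).  Liver and gut-wall enzyme pools are tracked
separately.  The driving exposure `I(t)` is, by default, the **unbound
concentration in whole liver tissue** (fu·C_liver) rather than the unbound
tissue-water concentration used for metabolism — the enzyme sits inside the
hepatocyte, where total-tissue-based unbound exposure is the more
appropriate scale.  This was a genuinely open structural choice: with the
water-unbound convention the model under-predicts poor-metabolizer exposure
(single-dose PM AUC −35% against the reference predictions), while the
tissue-unbound convention reproduces all three adult phenotype predictions
within ±15%.  The option `ModelOptions.tdi_driving` switches between the
two conventions.

**Elimination and absorption.**  Renal elimination is glomerular
filtration of unbound drug from arterial plasma, `CL_R = GFR · fu ·
gfr_fraction` with the filtration fraction fixed at 1.  Note that with the
printed metabolic constants this filtration clearance (~2.9 L/h in an
adult) is 10–30% of total clearance depending on phenotype, which is larger
than the ~2% urinary recovery reported clinically; the model keeps the
stated filtration assumption rather than introducing an unsupported
reabsorption term.  Oral doses dissolve in the gut lumen along a Weibull
profile (DT50 30 min, shape 1.29 for tablets; capsules and unspecified oral
forms reuse these), and dissolved drug is absorbed into the gut wall with a
first-order rate `ka = Peff · SA / V_lumen` built from the specific
intestinal permeability (2.81·10⁻⁵ cm/s) and the age-scaled intestinal
geometry of the physiology table.

**Integration.**  The ODE system (24 states: 16 compartments, dissolved
lumen amount, two enzyme states, five cumulative amounts) is integrated
with LSODA, restarting at every dose boundary (infusion start/stop, oral
dose times) so events are exact.  Default relative tolerance is 1e-8;
population-scale runs use 1e-6, at which halving the tolerance changes AUC
by far less than 0.1%.  Mass balance (compartments + cumulative metabolism
+ cumulative renal + lumen remainder = administered dose) holds within
0.5% at every output point and is enforced by test.

## Virtual individuals

Anatomy and physiology come from a packaged CSV of reference-person values
assembled from ICRP-style compilations: body mass, height, organ volumes,
regional blood-flow fractions, cardiac output, GFR, hematocrit and
intestinal geometry at anchor ages 0.25, 1, 5, 10, 15 and 18 years per sex,
linearly interpolated in age and constant from 18 to 80.  Children devote a
larger fraction of body mass to the liver and a larger fraction of cardiac
output to the brain; flow fractions are renormalised so organ flows sum
exactly to cardiac output.

Inter-individual variability is log-normal and multiplicative: geometric
CV 0.35 on each hepatic enzyme concentration and 0.10 on organ volumes,
flows and GFR (both configurable), plus a body-size factor (CV 0.10) when
anthropometric variability is enabled.  Cardiac output is recomputed as the
sum of perturbed flows, so flow balance is exact for every subject.  These
magnitudes are package conventions chosen to give concentration spreads of
the size typically displayed as 90% population prediction intervals; they
are not fitted quantities.

**Ontogeny.**  Hepatic enzyme abundance is scaled by a monotone-cubic
(PCHIP) age curve per enzyme: low at birth (0.25 / 0.15 / 0.30 of adult for
CYP2C19 / 3A4 / 2C9), exceeding the adult level through childhood (peaks
1.8 / 1.6 / 1.5 near age 3), declining to exactly 1 at 18 years.  The knots
are package defaults representing in-vivo activity meta-analyses in which
childhood enzyme activity exceeds adult levels; they were calibrated once
so that the simulated weight-normalised clearance ratio of NM children
(2–12 y) to NM adults falls in the documented 2–3× range (measured ≈2.2–2.5
at matched 4 mg/kg i.v. dosing), and all knots are configurable.

## Verification statistics

The non-compartmental layer uses the linear-up/log-down trapezoid; AUC to
infinity adds `C_last/λz` with λz from a terminal log-linear regression
(last three positive samples by default, or an explicit terminal window —
simulated single-dose analyses here use 12–24 h, a typical clinical
sampling span).  Model verification mirrors standard PBPK practice: the
predicted/observed ratio per study record, the fold deviation
max(r, 1/r) with the 2-fold acceptance and 0.8–1.25 stringent bands
(bounds inclusive; required to reproduce the printed pediatric Cmax
fraction of 73%), percentages rounded half-up, and the coverage of observed
points by the simulated 5th–95th percentile band.  Recomputing the adult
stringent fractions from the packaged 92-record table yields 74% (AUC) and
78–83% (Cmax) depending on pooling, close to but not exactly the published
78%/85%; the boundary-counting convention behind the published figures is
not recoverable, so the recomputation is reported rather than forced.

## Dose optimization

For each cohort (age band × CYP2C19 phenotype), 100 virtual subjects
receive b.i.d. i.v. maintenance dosing to day 7 (approximate steady state;
the evaluation day is a package choice) and the individual AUC over the
final 24 h is computed.  The PK/PD index is fAUC24/MIC with fu = 0.42 and
target ≥ 25 (boundary inclusive).  PTA at a MIC is the fraction of subjects
attaining the target; CFR for a species is PTA weighted by its MIC
frequency distribution; a dose is adequate for a genus when **every**
species reaches CFR ≥ 80% (minimum over species, not the frequency-weighted
average).  The recommended dose is the smallest adequate candidate on an
integer 1–14 mg/kg grid, found by scan or bisection (equivalent because CFR
is non-decreasing in dose for a fixed cohort).  IM recommendations use the
IM-with-\*1 abundance when applied clinically; the packaged default "IM"
pool (0.46 µmol/L) is used where the diplotype is unresolved.

## Synthetic data

The MIC panel (4 *Aspergillus*, 14 *Candida* species) is **synthetic**:
discretised log2-normal histograms on a two-fold dilution grid with modal
MICs chosen from field-typical susceptibility (Candida modal MICs
0.016–0.25 mg/L, Aspergillus 0.5–1 mg/L).  It reproduces the qualitative
structure real surveillance distributions have — unimodal wild-type peaks,
the genus-level susceptibility contrast — but not real frequencies, so
absolute CFR values and recommended doses are panel-dependent; only their
orderings (across phenotype, age and genus) are meaningful, and those are
what the acceptance suite asserts.  A loader accepts real EUCAST-style CSV
exports with the same layout.  Closed-form PK curve generators
(one-compartment bolus/infusion, biexponential, optional log-normal noise)
provide independent oracles for the NCA layer.

## Problem sizes and numerical choices

Population verification runs use 100 subjects (the study-design size);
the dose-recommendation ordering tests use 30-subject cohorts and shared
AUC caches across genera, which leaves the orderings stable while keeping
the suite quick.  Solver tolerances, the terminal-regression window, the
inclusive fold-range bounds and the half-up percentage rounding are all
stated above and fixed in code; degenerate inputs (zero dose, empty MIC
mass, unknown phenotype labels, windows outside the simulated grid) raise
explicit errors rather than returning silent zeros.

## Known limitations

- Perfusion-limited distribution throughout; no explicit cellular
  permeability step, hence the underestimated Vss noted above.
- No transporters, no metabolite (N-oxide) kinetics, no FMO3 route, no
  drug–drug interactions, no enterohepatic recirculation.
- Renal filtration at the full stated fraction over-represents urinary
  recovery relative to clinical data (see above).
- The pediatric model is verified for i.v. dosing only; oral simulation in
  children runs but is unverified.
- Disease states, obesity, pregnancy and preterm neonates are out of scope;
  the physiology table spans 0.25–80 years.
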