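"""Generate the packaged age/sex reference physiology CSV from ICRP-style anchors.

Anchors follow ICRP reference-person compilations (organ masses, blood volume,
cardiac output, GFR) at ages 0.25, 1, 5, 10, 15 and adult; adult values are
held constant from 18 y.  Run once; output committed as package data.
"""

import pandas as pd

ORGANS = [
    "lung", "brain", "heart", "kidney", "liver", "spleen", "gut_wall",
    "stomach", "pancreas", "muscle", "adipose", "skin", "bone", "gonads",
]

# organ masses in grams at anchor ages (male)
MASS_M = {
    #        0.25    1      5      10     15     adult
    "lung":    [70,   80,   125,   210,   330,   500],
    "brain":  [600,  950,  1245,  1310,  1420,  1450],
    "heart":   [30,   50,    85,   140,   230,   330],
    "kidney":  [45,   70,   110,   180,   250,   310],
    "liver":  [200,  330,   570,   830,  1300,  1800],
    "spleen":  [15,   29,    50,    80,   130,   150],
    "gut_wall":[150,  220,   370,   550,   830,  1020],
    "stomach": [30,   50,    85,   120,   140,   150],
    "pancreas":[10,   20,    35,    60,   110,   140],
    "muscle": [1200, 1900,  5600, 11000, 24000, 29000],
    "adipose":[1300, 2300,  3500,  6000,  8500, 14600],
    "skin":   [250,  350,   900,  1500,  2500,  3300],
    "bone":   [900, 1700,  3300,  5400,  8600, 10500],
    "gonads":  [1.0,  1.5,   2.0,   4.0,  25.0,  35.0],
}
MASS_F = {
    "lung":    [68,   76,   120,   200,   300,   420],
    "brain":  [580,  900,  1180,  1260,  1300,  1300],
    "heart":   [28,   46,    80,   130,   220,   250],
    "kidney":  [43,   65,   105,   170,   240,   275],
    "liver":  [190,  320,   550,   810,  1300,  1400],
    "spleen":  [14,   27,    48,    80,   130,   130],
    "gut_wall":[145,  210,   355,   530,   800,   920],
    "stomach": [28,   47,    82,   115,   130,   140],
    "pancreas":[10,   19,    34,    58,   100,   120],
    "muscle": [1100, 1800,  5300, 10500, 17000, 17500],
    "adipose":[1300, 2400,  3800,  7000, 14000, 18000],
    "skin":   [240,  330,   850,  1400,  2000,  2300],
    "bone":   [850, 1600,  3100,  5100,  7200,  7800],
    "gonads":  [0.5,  0.8,   2.0,   4.0,  10.0,  11.0],
}

# soft tissue density ~1.0 g/mL; adipose 0.92; skeleton (with marrow) 1.3
DENSITY = {o: 1.0 for o in ORGANS}
DENSITY["adipose"] = 0.92
DENSITY["bone"] = 1.3

AGES = [0.25, 1, 5, 10, 15, 18]
WEIGHT_M = [6.0, 10.0, 19.0, 32.0, 56.0, 73.0]
HEIGHT_M = [61, 76, 109, 138, 167, 176]
WEIGHT_F = [5.6, 9.5, 18.0, 31.0, 53.0, 60.0]
HEIGHT_F = [60, 74, 108, 137, 161, 163]

BLOOD_ML_M = [480, 800, 1500, 2500, 4400, 5600]
BLOOD_ML_F = [450, 760, 1400, 2400, 3900, 4100]
VENOUS_FRACTION = 0.72

CO_L_MIN_M = [0.9, 1.5, 2.8, 3.9, 5.5, 6.5]
CO_L_MIN_F = [0.85, 1.4, 2.7, 3.7, 5.0, 5.9]

GFR_ML_MIN_M = [20, 45, 65, 90, 110, 115]
GFR_ML_MIN_F = [19, 43, 62, 85, 100, 100]

HCT_M = [0.35, 0.36, 0.37, 0.39, 0.42, 0.44]
HCT_F = [0.35, 0.36, 0.37, 0.39, 0.40, 0.40]

# regional blood flow fractions of cardiac output (renormalised to 1);
# children divert relatively more flow to the brain, less to muscle
FLOW_FRACTIONS = {
    #          0.25   1      5      10     15     adult
    "brain":  [0.25, 0.28, 0.30,  0.25,  0.15,  0.12],
    "heart":  [0.04, 0.04, 0.04,  0.04,  0.04,  0.04],
    "kidney": [0.15, 0.16, 0.19,  0.19,  0.19,  0.19],
    "liver":  [0.065, 0.065, 0.065, 0.065, 0.065, 0.065],  # hepatic artery
    "gut_wall":[0.13, 0.13, 0.13,  0.13,  0.13,  0.13],
    "stomach":[0.01, 0.01, 0.01,  0.01,  0.01,  0.01],
    "pancreas":[0.01, 0.01, 0.01,  0.01,  0.01,  0.01],
    "spleen": [0.03, 0.03, 0.03,  0.03,  0.03,  0.03],
    "muscle": [0.07, 0.07, 0.08,  0.10,  0.14,  0.17],
    "adipose":[0.03, 0.03, 0.03,  0.04,  0.05,  0.05],
    "skin":   [0.05, 0.05, 0.05,  0.05,  0.05,  0.05],
    "bone":   [0.05, 0.05, 0.05,  0.05,  0.05,  0.05],
    "gonads": [0.0005]*6,
}

SI_SURFACE_CM2_M = [900, 1500, 2700, 3900, 5600, 6600]
SI_LUMEN_L_M = [0.07, 0.11, 0.20, 0.29, 0.42, 0.50]

rows = []
for sex, mass, wt, ht, blood, co, gfr, hct in [
    ("male", MASS_M, WEIGHT_M, HEIGHT_M, BLOOD_ML_M, CO_L_MIN_M, GFR_ML_MIN_M, HCT_M),
    ("female", MASS_F, WEIGHT_F, HEIGHT_F, BLOOD_ML_F, CO_L_MIN_F, GFR_ML_MIN_F, HCT_F),
]:
    for i, age in enumerate(AGES):
        row = {"age_yr": age, "sex": sex, "weight_kg": wt[i], "height_cm": ht[i]}
        for o in ORGANS:
            row[f"v_{o}"] = round(mass[o][i] / DENSITY[o] / 1000.0, 5)
        vb = blood[i] / 1000.0
        row["v_venous_blood"] = round(vb * VENOUS_FRACTION, 5)
        row["v_arterial_blood"] = round(vb * (1 - VENOUS_FRACTION), 5)
        co_l_h = co[i] * 60.0
        fr_sum = sum(FLOW_FRACTIONS[o][i] for o in FLOW_FRACTIONS)
        for o in FLOW_FRACTIONS:
            row[f"q_{o}"] = round(FLOW_FRACTIONS[o][i] / fr_sum * co_l_h, 4)
        row["q_lung"] = round(co_l_h, 4)
        row["co_l_h"] = round(co_l_h, 4)
        row["gfr_ml_min"] = gfr[i]
        row["hematocrit"] = hct[i]
        # intestinal absorption geometry scales roughly with body surface area
        scale = (wt[i] * ht[i]) ** 0.5 / (WEIGHT_M[-1] * HEIGHT_M[-1]) ** 0.5
        row["si_surface_cm2"] = round(SI_SURFACE_CM2_M[-1] * scale, 0)
        row["si_lumen_l"] = round(SI_LUMEN_L_M[-1] * scale, 4)
        rows.append(row)
    # adult values constant beyond 18 y
    for extra_age in (30, 80):
        r = dict(rows[-1])
        r["age_yr"] = extra_age
        rows.append(r)

df = pd.DataFrame(rows)
df.to_csv("src/voripbpk/data/reference_physiology.csv", index=False)
print(df.head())
print("cols:", len(df.columns), "rows:", len(df))
# sanity: organ volumes vs body weight
for _, r in df.iterrows():
    tot = sum(r[f"v_{o}"] for o in ORGANS) + r.v_venous_blood + r.v_arterial_blood
    assert tot < r.weight_kg / 1.05, (r.age_yr, r.sex, tot, r.weight_kg / 1.05)
print("volume bound OK")
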