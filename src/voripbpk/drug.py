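"""Voriconazole-specific constants and genotype/age scaling of metabolic enzymes.

The drug is a weakly basic, moderately lipophilic triazole antifungal that is
cleared almost entirely by hepatic CYP2C19, CYP3A4 and CYP2C9; only ~2% of a
dose is filtered unchanged into urine.  This module holds the physicochemical
and enzymological input parameters, the CYP2C19 phenotype -> hepatic enzyme
abundance table, in-vivo enzyme ontogeny curves for children, and the
Poulin-Theil tissue:plasma partition-coefficient calculation.

Internal unit system: amounts in umol, concentrations in umol/L, time in
hours at the simulation layer (rate constants below are stated per minute,
as conventionally tabulated, and converted where used).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.interpolate import PchipInterpolator

ENZYMES = ("CYP2C19", "CYP3A4", "CYP2C9")

#: hepatic CYP2C19 reference concentration (umol/L) by metaboliser phenotype.
#: "IM" is the pooled value used when a study does not resolve the diplotype.
PHENOTYPE_REFERENCE = {
    "UM": 1.41,
    "RM": 1.36,
    "NM": 0.76,
    "IM_star17": 0.63,
    "IM": 0.46,
    "IM_star1": 0.29,
    "PM": 0.0,
}

#: adult hepatic reference concentrations (umol/L) for the non-polymorphic
#: enzymes (CYP2C19 comes from PHENOTYPE_REFERENCE).
ADULT_ENZYME_REFERENCE = {"CYP3A4": 4.32, "CYP2C9": 3.84}


class Formulation(BaseModel):
    """Weibull dissolution parameters for the immediate-release tablet."""

    dt50_min: float = Field(30.0, gt=0, description="time to 50% dissolved, min")
    weibull_shape: float = Field(1.29, gt=0)


class DrugParameters(BaseModel):
    """Physicochemistry, permeability and renal handling (defaults: voriconazole)."""

    molecular_weight: float = Field(349.3, gt=0, description="g/mol")
    fu_plasma: float = Field(0.42, gt=0, le=1, description="unbound fraction in plasma")
    logp: float = 1.65
    pka_base: float = 1.76
    solubility_mg_ml: float = Field(3.2, gt=0, description="at pH 1.0")
    intestinal_permeability_cm_s: float = Field(2.81e-5, gt=0)
    gfr_fraction: float = Field(1.0, ge=0, description="fraction of GFR available for filtration")
    formulation: Formulation = Field(default_factory=Formulation)

    @property
    def mg_per_umol(self) -> float:
        return self.molecular_weight / 1000.0


@dataclass(frozen=True)
class EnzymeKinetics:
    """Michaelis-Menten constants of one metabolising enzyme.

    km in umol/L (unbound liver water concentration scale); kcat in 1/min
    per umol/L of enzyme, i.e. in-vitro Vmax per enzyme content.
    """

    enzyme: str
    km: float
    kcat: float

    def __post_init__(self):
        if self.km <= 0:
            raise ValueError("km must be > 0")
        if self.kcat < 0:
            raise ValueError("kcat must be >= 0")


def default_kinetics() -> dict[str, EnzymeKinetics]:
    return {
        "CYP2C19": EnzymeKinetics("CYP2C19", km=3.5, kcat=1.19),
        "CYP3A4": EnzymeKinetics("CYP3A4", km=11.0, kcat=2.3),
        "CYP2C9": EnzymeKinetics("CYP2C9", km=20.0, kcat=0.0556),
    }


@dataclass(frozen=True)
class TDIParameters:
    """Mechanism-based (time-dependent) inactivation of CYP3A4.

    kinact: maximal inactivation rate (1/min); ki: inhibitor concentration
    at half-maximal inactivation (umol/L); kdeg: natural enzyme turnover
    (1/min, default ~36 h turnover half-life, the conventional hepatic CYP3A4
    value); e0: baseline enzyme concentration of the individual (umol/L).
    """

    kinact: float = 0.04
    ki: float = 9.33
    kdeg: float = 3.2e-4
    e0: float = ADULT_ENZYME_REFERENCE["CYP3A4"]

    def __post_init__(self):
        if self.kinact <= 0 or self.ki <= 0 or self.kdeg <= 0:
            raise ValueError("kinact, ki and kdeg must be > 0")


def phenotype_reference_concentration(phenotype: str) -> float:
    """Hepatic CYP2C19 concentration (umol/L) for a metaboliser phenotype."""
    key = "IM" if phenotype == "IM_unspecified" else phenotype
    try:
        return PHENOTYPE_REFERENCE[key]
    except KeyError:
        raise KeyError(
            f"unknown CYP2C19 phenotype {phenotype!r}; "
            f"expected one of {sorted(PHENOTYPE_REFERENCE)}"
        ) from None


# ---------------------------------------------------------------------------
# Ontogeny
# ---------------------------------------------------------------------------

ADULT_AGE = 18.0

#: default in-vivo ontogeny knots (age in years -> multiple of adult
#: abundance).  Activity is low at birth, rises above the adult level during
#: childhood, and declines back to 1 by 18 y, consistent with in-vivo
#: clearance meta-analyses showing ~2-3x higher weight-normalised clearance
#: in children.  Knots are package defaults and fully configurable.
DEFAULT_ONTOGENY_KNOTS: dict[str, list[tuple[float, float]]] = {
    "CYP2C19": [(0.0, 0.25), (1.0, 1.10), (3.0, 1.80), (6.0, 1.70),
                (12.0, 1.35), (18.0, 1.0), (30.0, 1.0), (80.0, 1.0)],
    "CYP3A4": [(0.0, 0.15), (1.0, 1.05), (3.0, 1.60), (6.0, 1.50),
               (12.0, 1.25), (18.0, 1.0), (30.0, 1.0), (80.0, 1.0)],
    "CYP2C9": [(0.0, 0.30), (1.0, 1.05), (3.0, 1.50), (6.0, 1.40),
               (12.0, 1.20), (18.0, 1.0), (30.0, 1.0), (80.0, 1.0)],
}


@dataclass
class OntogenyProfile:
    """Monotone-cubic (PCHIP) ontogeny curve for one enzyme."""

    enzyme: str
    knots: list[tuple[float, float]]
    _interp: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self):
        ages = np.array([a for a, _ in self.knots], dtype=float)
        facs = np.array([f for _, f in self.knots], dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError("knot ages must be strictly increasing")
        if np.any(facs < 0):
            raise ValueError("ontogeny factors must be >= 0")
        object.__setattr__(self, "_interp", PchipInterpolator(ages, facs, extrapolate=False))

    def __call__(self, age: float | np.ndarray) -> float | np.ndarray:
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be >= 0")
        out = np.where(age >= ADULT_AGE, 1.0, self._interp(np.clip(age, 0, ADULT_AGE)))
        return float(out) if out.ndim == 0 else out


DEFAULT_ONTOGENY = {e: OntogenyProfile(e, k) for e, k in DEFAULT_ONTOGENY_KNOTS.items()}


def ontogeny_factor(enzyme: str, age: float,
                    profiles: dict[str, OntogenyProfile] | None = None) -> float:
    """Multiplier of the adult hepatic enzyme concentration at a given age."""
    profiles = profiles or DEFAULT_ONTOGENY
    if enzyme not in profiles:
        raise KeyError(f"no ontogeny profile for {enzyme!r}")
    return profiles[enzyme](age)


def effective_enzyme_concentration(phenotype: str, enzyme: str, age: float,
                                   variability_draw: float = 1.0,
                                   profiles: dict[str, OntogenyProfile] | None = None) -> float:
    """Hepatic enzyme concentration (umol/L): reference x ontogeny x variability.

    The CYP2C19 reference is phenotype-specific (exactly 0 for PMs, which is
    absorbing under the multiplicative scalings); CYP3A4/CYP2C9 use the adult
    reference irrespective of CYP2C19 phenotype.
    """
    if enzyme == "CYP2C19":
        ref = phenotype_reference_concentration(phenotype)
    else:
        ref = ADULT_ENZYME_REFERENCE[enzyme]
    return ref * ontogeny_factor(enzyme, age, profiles) * variability_draw


# ---------------------------------------------------------------------------
# Poulin-Theil tissue:plasma partition coefficients
# ---------------------------------------------------------------------------

def load_tissue_composition() -> pd.DataFrame:
    """Packaged fractional tissue composition (water / neutral lipid / phospholipid)."""
    with resources.files("voripbpk.data").joinpath("tissue_composition.csv").open() as fh:
        return pd.read_csv(fh)


def _pt_solvent_term(p: float, f_nl: float, f_ph: float, f_w: float) -> float:
    # lipid term: neutral lipid plus 30% of phospholipid behaves like oil;
    # aqueous term: water plus the remaining 70% of phospholipid
    return p * (f_nl + 0.3 * f_ph) + (f_w + 0.7 * f_ph)


def partition_coefficients(drug: DrugParameters,
                           composition: pd.DataFrame | None = None,
                           fu_tissue: float | None = None) -> dict[str, float]:
    """Tissue:plasma partition coefficients by the Poulin-Theil method.

    Non-adipose tissues use the octanol:water partition coefficient and a
    tissue unbound fraction conventionally set to half the plasma binding
    strength; adipose uses the vegetable-oil:water coefficient
    (log D_vo:w = 1.115 logP - 1.35) and no tissue-binding correction.
    """
    comp = composition if composition is not None else load_tissue_composition()
    required = {"organ", "f_water", "f_neutral_lipid", "f_phospholipid"}
    if not required.issubset(comp.columns):
        raise ValueError(f"composition table must have columns {sorted(required)}")
    rows = {r.organ: r for r in comp.itertuples(index=False)}
    if "plasma" not in rows:
        raise ValueError("composition table must include a 'plasma' row")

    p_ow = 10.0 ** drug.logp
    d_vow = 10.0 ** (1.115 * drug.logp - 1.35)
    fu_p = drug.fu_plasma
    if fu_tissue is None:
        fu_t = 1.0 / (1.0 + 0.5 * (1.0 - fu_p) / fu_p)
    else:
        fu_t = fu_tissue

    pl = rows["plasma"]
    kp: dict[str, float] = {}
    for organ, r in rows.items():
        if organ == "plasma":
            continue
        p = d_vow if organ == "adipose" else p_ow
        num = _pt_solvent_term(p, r.f_neutral_lipid, r.f_phospholipid, r.f_water)
        den = _pt_solvent_term(p, pl.f_neutral_lipid, pl.f_phospholipid, pl.f_water)
        binding = fu_p if organ == "adipose" else fu_p / fu_t
        kp[organ] = num / den * binding
        if kp[organ] <= 0:
            raise ValueError(f"non-positive Kp computed for {organ}")
    return kp
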