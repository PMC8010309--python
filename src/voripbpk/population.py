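"""Virtual adult and pediatric individuals with age/sex-dependent physiology.

Anatomy and physiology (body size, organ volumes, regional blood flows, GFR,
hematocrit) come from a packaged CSV of reference-person values assembled
from published ICRP-type compilations, linearly interpolated in age and
constant from 18 y.  Inter-individual variability is modelled as log-normal
multiplicative noise on enzyme concentrations (geometric CV 0.35 by default)
and on organ flows/volumes (CV 0.10); cardiac output is recomputed as the
sum of perturbed regional flows so that flow balance holds exactly for every
individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import drug as _drug

#: perfused organs of the whole-body model (lung is in series with the heart
#: and carries the full cardiac output; the rest are in parallel).
ORGANS = [
    "lung", "brain", "heart", "kidney", "liver", "spleen", "gut_wall",
    "stomach", "pancreas", "muscle", "adipose", "skin", "bone", "gonads",
]
BLOOD_COMPARTMENTS = ["arterial_blood", "venous_blood"]
#: organs whose venous outflow drains into the portal vein (to the liver)
PORTAL_ORGANS = ["gut_wall", "stomach", "pancreas", "spleen"]

AGE_MIN, AGE_MAX = 0.25, 80.0

Sex = Literal["male", "female"]


class VariabilitySpec(BaseModel):
    """Magnitudes of inter-individual variability (geometric CVs)."""

    enzyme_gcv: float = Field(0.35, ge=0)
    flow_volume_gcv: float = Field(0.10, ge=0)
    anthropometric_sd_mode: Literal["none", "growth-table"] = "growth-table"

    @classmethod
    def none(cls) -> "VariabilitySpec":
        return cls(enzyme_gcv=0.0, flow_volume_gcv=0.0, anthropometric_sd_mode="none")


class PopulationSpec(BaseModel):
    """Specification of a virtual cohort."""

    n: int = Field(..., ge=1)
    age_range: tuple[float, float]
    male_fraction: float = Field(..., ge=0, le=1)
    phenotype_mix: dict[str, float]
    variability: VariabilitySpec = Field(default_factory=VariabilitySpec)
    seed: int = 0
    age_mean: float | None = None
    age_sd: float | None = None

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.age_range
        if not (AGE_MIN <= lo <= hi <= AGE_MAX):
            raise ValueError(f"age_range must lie within [{AGE_MIN}, {AGE_MAX}]")
        tot = sum(self.phenotype_mix.values())
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"phenotype fractions must sum to 1 (got {tot})")
        for ph in self.phenotype_mix:
            try:
                _drug.phenotype_reference_concentration(ph)
            except KeyError as exc:
                raise ValueError(str(exc)) from None
        if (self.age_mean is None) != (self.age_sd is None):
            raise ValueError("age_mean and age_sd must be given together")
        return self


@dataclass
class IndividualPhysiology:
    """One virtual subject: demographics, anatomy, flows and enzyme content."""

    age: float
    sex: Sex
    phenotype: str
    body_weight: float            # kg
    height: float                 # cm
    organ_volumes: dict[str, float]   # L, keys: ORGANS + BLOOD_COMPARTMENTS
    blood_flows: dict[str, float]     # L/h, keys: ORGANS (lung = cardiac output)
    cardiac_output: float         # L/h
    gfr: float                    # mL/min
    hematocrit: float
    enzyme_liver_conc: dict[str, float]  # umol/L
    si_surface_cm2: float = 6600.0
    si_lumen_l: float = 0.5

    def validate(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")
        for name, v in self.organ_volumes.items():
            if v <= 0:
                raise ValueError(f"volume of {name} must be > 0")
        for name, q in self.blood_flows.items():
            if q <= 0:
                raise ValueError(f"flow of {name} must be > 0")
        systemic = sum(q for o, q in self.blood_flows.items() if o != "lung")
        if abs(systemic - self.cardiac_output) > 0.01 * self.cardiac_output:
            raise ValueError("organ flows do not balance cardiac output")
        if any(c < 0 for c in self.enzyme_liver_conc.values()):
            raise ValueError("enzyme concentrations must be >= 0")


class UnsupportedAgeError(ValueError):
    pass


_TABLE_CACHE: pd.DataFrame | None = None


def load_reference_table() -> pd.DataFrame:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        with resources.files("voripbpk.data").joinpath("reference_physiology.csv").open() as fh:
            _TABLE_CACHE = pd.read_csv(fh)
    return _TABLE_CACHE


def reference_physiology(age: float, sex: Sex) -> dict:
    """Reference anatomy/physiology at (age, sex), piecewise-linear in age.

    Returns a dict with weight_kg, height_cm, organ_volumes (L),
    blood_flows (L/h), co_l_h, gfr_ml_min, hematocrit and intestinal
    absorption geometry.  Adult values are constant beyond 18 y.
    """
    if not (AGE_MIN <= age <= AGE_MAX):
        raise UnsupportedAgeError(
            f"age {age} outside supported range [{AGE_MIN}, {AGE_MAX}]")
    tab = load_reference_table()
    sub = tab[tab.sex == sex].sort_values("age_yr")
    if sub.empty:
        raise ValueError(f"unknown sex {sex!r}")
    ages = sub.age_yr.to_numpy()
    row = {c: float(np.interp(age, ages, sub[c].to_numpy()))
           for c in sub.columns if c not in ("age_yr", "sex")}
    return {
        "weight_kg": row["weight_kg"],
        "height_cm": row["height_cm"],
        "organ_volumes": {o: row[f"v_{o}"] for o in ORGANS + BLOOD_COMPARTMENTS},
        "blood_flows": {o: row[f"q_{o}"] for o in ORGANS},
        "co_l_h": row["co_l_h"],
        "gfr_ml_min": row["gfr_ml_min"],
        "hematocrit": row["hematocrit"],
        "si_surface_cm2": row["si_surface_cm2"],
        "si_lumen_l": row["si_lumen_l"],
    }


def _lognormal_draw(rng: np.random.Generator, gcv: float, size=None):
    """Multiplicative log-normal factor with geometric CV `gcv` and median 1."""
    if gcv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + gcv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_individual(age: float, sex: Sex, phenotype: str,
                        variability: VariabilitySpec | None = None,
                        seed: int | np.random.Generator | None = None,
                        ontogeny: dict[str, _drug.OntogenyProfile] | None = None,
                        ) -> IndividualPhysiology:
    """Build one virtual subject.

    With variability disabled the result is deterministic in
    (age, sex, phenotype); with a fixed seed it is reproducible bit-for-bit.
    """
    var = variability if variability is not None else VariabilitySpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = reference_physiology(age, sex)

    weight, height = ref["weight_kg"], ref["height_cm"]
    size_factor = 1.0
    if var.anthropometric_sd_mode == "growth-table":
        size_factor = float(_lognormal_draw(rng, 0.10))
        weight *= size_factor
        height *= float(_lognormal_draw(rng, 0.035))

    volumes = {}
    for o in ORGANS + BLOOD_COMPARTMENTS:
        volumes[o] = ref["organ_volumes"][o] * size_factor * float(
            _lognormal_draw(rng, var.flow_volume_gcv))
    flows = {}
    for o in ORGANS:
        if o == "lung":
            continue
        flows[o] = ref["blood_flows"][o] * size_factor * float(
            _lognormal_draw(rng, var.flow_volume_gcv))
    co = sum(flows.values())           # exact flow balance by construction
    flows["lung"] = co
    gfr = ref["gfr_ml_min"] * size_factor * float(_lognormal_draw(rng, var.flow_volume_gcv))

    enzymes = {}
    for enz in _drug.ENZYMES:
        draw = float(_lognormal_draw(rng, var.enzyme_gcv))
        enzymes[enz] = _drug.effective_enzyme_concentration(
            phenotype, enz, age, draw, profiles=ontogeny)

    ind = IndividualPhysiology(
        age=age, sex=sex, phenotype=phenotype,
        body_weight=weight, height=height,
        organ_volumes=volumes, blood_flows=flows, cardiac_output=co,
        gfr=gfr, hematocrit=ref["hematocrit"], enzyme_liver_conc=enzymes,
        si_surface_cm2=ref["si_surface_cm2"] * size_factor,
        si_lumen_l=ref["si_lumen_l"] * size_factor,
    )
    ind.validate()
    return ind


def generate_population(spec: PopulationSpec,
                        ontogeny: dict[str, _drug.OntogenyProfile] | None = None,
                        ) -> list[IndividualPhysiology]:
    """Generate `spec.n` independent virtual subjects (deterministic in seed)."""
    master = np.random.default_rng(spec.seed)
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n)
    phenos = list(spec.phenotype_mix)
    probs = np.array([spec.phenotype_mix[p] for p in phenos], dtype=float)
    probs = probs / probs.sum()

    people = []
    lo, hi = spec.age_range
    for i in range(spec.n):
        sex: Sex = "male" if master.random() < spec.male_fraction else "female"
        if spec.age_mean is not None:
            age = float(np.clip(master.normal(spec.age_mean, spec.age_sd), lo, hi))
        else:
            age = float(master.uniform(lo, hi))
        phenotype = phenos[int(master.choice(len(phenos), p=probs))]
        people.append(generate_individual(
            age, sex, phenotype, spec.variability,
            seed=np.random.default_rng(child_seeds[i]), ontogeny=ontogeny))
    return people
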