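"""PK/PD target attainment and pediatric dose optimization.

The efficacy index is the unbound 24-h AUC over the MIC, fAUC24/MIC, with
target >= 25 (boundary inclusive).  PTA at a given MIC is the fraction of a
virtual population attaining the target; CFR weights PTA over a species'
MIC frequency distribution.  A b.i.d. maintenance dose is deemed adequate
for a fungal genus when every species in the genus reaches CFR >= 80%, and
the recommended dose is the smallest adequate candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import nca
from .drug import DrugParameters, TDIParameters
from .engine import DosingRegimen, ModelOptions, simulate_population
from .population import PopulationSpec, VariabilitySpec, generate_population

DEFAULT_FU = 0.42
DEFAULT_TARGET = 25.0
DEFAULT_CFR_CRITERION = 80.0


@dataclass
class MICDistribution:
    """Species-level MIC histogram on a two-fold dilution grid."""

    species: str
    genus: str
    mics: np.ndarray        # mg/L, strictly increasing powers of 2 x base
    frequencies: np.ndarray  # sum to 1

    def __post_init__(self):
        self.mics = np.asarray(self.mics, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.mics.ndim != 1 or self.mics.size == 0:
            raise ValueError("empty MIC grid")
        order = np.argsort(self.mics)
        self.mics = self.mics[order]
        self.frequencies = self.frequencies[order]
        if np.any(self.mics <= 0):
            raise ValueError("MICs must be > 0")
        ratios = self.mics[1:] / self.mics[:-1]
        if np.any(np.abs(np.log2(ratios) - np.round(np.log2(ratios))) > 1e-6):
            raise ValueError("MIC grid must lie on two-fold dilutions")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be >= 0")
        if abs(self.frequencies.sum() - 1.0) > 1e-6:
            raise ValueError("frequencies must sum to 1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list["MICDistribution"]:
        """Parse a tidy table with columns species, genus, mic_mg_l, frequency."""
        out = []
        for (sp, gen), g in df.groupby(["species", "genus"], sort=True):
            out.append(cls(sp, gen, g.mic_mg_l.to_numpy(),
                           g.frequency.to_numpy()))
        return out


@dataclass
class PTAResult:
    dose_label: str
    mic: float
    pta: float


@dataclass
class CFRResult:
    species: str
    dose_label: str
    cfr: float   # percent


@dataclass
class DoseRecommendation:
    age_group: tuple[float, float]
    phenotype: str
    genus: str
    dose_mg_kg: float | None       # None = no adequate candidate
    min_species_cfr: float | None  # percent, at the recommended dose
    cfr_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def adequate(self) -> bool:
        return self.dose_mg_kg is not None


def fauc_mic(auc_24h: float | np.ndarray, mic: float,
             fu: float = DEFAULT_FU) -> float | np.ndarray:
    """Unbound AUC24/MIC index: fu * AUC24 / MIC."""
    if mic <= 0:
        raise ValueError("MIC must be > 0")
    return fu * np.asarray(auc_24h, dtype=float) / mic


def pta(auc_24h_values: Sequence[float], mic: float, fu: float = DEFAULT_FU,
        target: float = DEFAULT_TARGET) -> float:
    """Fraction of subjects with fAUC24/MIC >= target (boundary attains)."""
    aucs = np.asarray(auc_24h_values, dtype=float)
    if aucs.size == 0:
        raise ValueError("empty population")
    return float(np.mean(fauc_mic(aucs, mic, fu) >= target))


def pta_curve(auc_24h_values: Sequence[float], mics: Sequence[float],
              fu: float = DEFAULT_FU, target: float = DEFAULT_TARGET,
              dose_label: str = "") -> list[PTAResult]:
    return [PTAResult(dose_label, float(m), pta(auc_24h_values, float(m), fu, target))
            for m in mics]


def cfr(pta_by_mic: dict[float, float] | Sequence[PTAResult],
        dist: MICDistribution) -> float:
    """Cumulative fraction of response (%) = sum_i PTA(MIC_i) * freq_i * 100."""
    if not isinstance(pta_by_mic, dict):
        pta_by_mic = {r.mic: r.pta for r in pta_by_mic}
    total = 0.0
    for mic, freq in zip(dist.mics, dist.frequencies):
        if freq == 0.0:
            continue
        match = [m for m in pta_by_mic if abs(np.log2(m / mic)) < 1e-9]
        if not match:
            raise ValueError(f"no PTA available at MIC {mic} for {dist.species}")
        total += pta_by_mic[match[0]] * freq
    return 100.0 * total


def _default_regimen(dose_mg_kg: float) -> DosingRegimen:
    """Maintenance-only b.i.d. i.v. regimen to day 7 (120-min infusions)."""
    return DosingRegimen.schedule(dose_mg_kg, interval_h=12.0, n_doses=14,
                                  route="iv_infusion", infusion_min=120.0,
                                  per_kg=True)


def simulate_auc24(population, dose_mg_kg: float,
                   regimen_builder: Callable[[float], DosingRegimen] = _default_regimen,
                   drug: DrugParameters | None = None,
                   tdi: TDIParameters | None | str = "default",
                   options: ModelOptions | None = None,
                   window: tuple[float, float] = (144.0, 168.0),
                   output_dt: float = 0.25) -> np.ndarray:
    """Per-subject steady-state AUC over 24 h (day 7 of b.i.d. maintenance)."""
    regimen = regimen_builder(dose_mg_kg)
    results = simulate_population(population, regimen, t_end=window[1],
                                  drug=drug, tdi=tdi, options=options,
                                  output_dt=output_dt)
    return np.array([nca.auc_trapezoid(r.t, r.conc_mg_l, *window)
                     for r in results])


def recommend_dose(age_group: tuple[float, float], phenotype: str, genus: str,
                   mic_distributions: Sequence[MICDistribution],
                   candidate_doses: Sequence[float] = tuple(range(1, 15)),
                   n_subjects: int = 100, seed: int = 0,
                   male_fraction: float = 0.5,
                   variability: VariabilitySpec | None = None,
                   fu: float = DEFAULT_FU, target: float = DEFAULT_TARGET,
                   criterion: float = DEFAULT_CFR_CRITERION,
                   auc24_fn: Callable[[float], np.ndarray] | None = None,
                   search: str = "bisect",
                   drug: DrugParameters | None = None,
                   options: ModelOptions | None = None) -> DoseRecommendation:
    """Smallest b.i.d. maintenance dose with min-over-species CFR >= criterion.

    Simulates one fixed virtual cohort (same subjects across doses) per
    (age group, phenotype, seed), computes each candidate's steady-state
    AUC24 distribution, and scans (or bisects, valid because CFR is
    non-decreasing in dose for a fixed cohort) for the smallest adequate
    candidate.  `auc24_fn` can replace the simulation step, e.g. in tests.
    Returns a "no adequate dose" result (dose None) rather than raising when
    no candidate attains the criterion.
    """
    doses = sorted(float(d) for d in candidate_doses)
    if not doses:
        raise ValueError("no candidate doses")
    species = [d for d in mic_distributions if d.genus == genus]
    if not species:
        raise ValueError(f"no MIC distributions for genus {genus!r}")

    if auc24_fn is None:
        spec = PopulationSpec(
            n=n_subjects, age_range=age_group, male_fraction=male_fraction,
            phenotype_mix={phenotype: 1.0},
            variability=variability or VariabilitySpec(), seed=seed)
        cohort = generate_population(spec)
        cache: dict[float, np.ndarray] = {}

        def auc24_fn(dose: float) -> np.ndarray:
            if dose not in cache:
                cache[dose] = simulate_auc24(cohort, dose, drug=drug,
                                             options=options)
            return cache[dose]

    rows = []
    evaluated: dict[float, float] = {}

    def min_cfr(dose: float) -> float:
        if dose in evaluated:
            return evaluated[dose]
        aucs = auc24_fn(dose)
        vals = []
        for dist in species:
            curve = {float(m): pta(aucs, float(m), fu, target)
                     for m in dist.mics[dist.frequencies > 0]}
            c = cfr(curve, dist)
            rows.append({"dose_mg_kg": dose, "species": dist.species, "cfr": c})
            vals.append(c)
        evaluated[dose] = min(vals)
        return evaluated[dose]

    best: float | None = None
    if search == "scan":
        for d in doses:
            if min_cfr(d) >= criterion:
                best = d
                break
    elif search == "bisect":
        lo, hi = 0, len(doses) - 1
        if min_cfr(doses[hi]) >= criterion:
            while lo < hi:
                mid = (lo + hi) // 2
                if min_cfr(doses[mid]) >= criterion:
                    hi = mid
                else:
                    lo = mid + 1
            best = doses[hi]
    else:
        raise ValueError("search must be 'scan' or 'bisect'")

    table = pd.DataFrame(rows).sort_values(["dose_mg_kg", "species"]).reset_index(drop=True)
    return DoseRecommendation(
        age_group=age_group, phenotype=phenotype, genus=genus,
        dose_mg_kg=best,
        min_species_cfr=evaluated.get(best) if best is not None else None,
        cfr_table=table)
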