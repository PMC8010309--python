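"""Synthetic inputs: MIC frequency distributions, closed-form PK curves, and
loaders for the packaged calibration/validation tables.

The packaged MIC histograms are SYNTHETIC: they emulate the shape of
EUCAST-style species distributions on a two-fold dilution grid (modal MIC
plus a discretised log2-normal spread) and carry realistic modal values per
species, but they are not EUCAST data.  A loader accepts real EUCAST CSV
exports in the same tidy layout (species, genus, mic_mg_l, frequency).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd

from .pkpd import MICDistribution

# ---------------------------------------------------------------------------
# MIC distributions
# ---------------------------------------------------------------------------

@dataclass
class SyntheticMICSpec:
    species: str
    genus: str
    modal_mic: float                  # mg/L, on the two-fold grid
    log2_spread: float                # dilution steps (sd of log2-normal)
    grid_min: float = 0.004
    grid_max: float = 16.0
    n_isolates: int | None = None     # if set, sample counts (seeded)
    seed: int = 0

    def __post_init__(self):
        if self.log2_spread <= 0:
            raise ValueError("spread must be > 0 (use a tiny value for point mass)")
        if not (self.grid_min < self.grid_max):
            raise ValueError("degenerate MIC grid bounds")


def generate_mic_distribution(spec: SyntheticMICSpec) -> MICDistribution:
    """Discretised log2-normal MIC histogram, normalised to 1."""
    lo = np.floor(np.log2(spec.grid_min))
    hi = np.ceil(np.log2(spec.grid_max))
    grid_log2 = np.arange(lo, hi + 0.5)
    mics = 2.0 ** grid_log2
    z = (grid_log2 - np.log2(spec.modal_mic)) / spec.log2_spread
    w = np.exp(-0.5 * z * z)
    if w.sum() == 0:
        raise ValueError("spread too small for the grid; no mass captured")
    freqs = w / w.sum()
    if spec.n_isolates is not None:
        rng = np.random.default_rng(spec.seed)
        counts = rng.multinomial(spec.n_isolates, freqs)
        freqs = counts / counts.sum()
    keep = freqs > 1e-12
    return MICDistribution(spec.species, spec.genus, mics[keep],
                           freqs[keep] / freqs[keep].sum())


#: default synthetic species set: 4 Aspergillus + 14 Candida, modal MICs
#: chosen to mirror the well-known susceptibility contrast between the two
#: genera (Candida far more susceptible to voriconazole than Aspergillus).
DEFAULT_MIC_SPECS: list[SyntheticMICSpec] = [
    SyntheticMICSpec("Aspergillus fumigatus", "Aspergillus", 0.5, 0.8),
    SyntheticMICSpec("Aspergillus flavus", "Aspergillus", 1.0, 0.8),
    SyntheticMICSpec("Aspergillus niger", "Aspergillus", 1.0, 0.8),
    SyntheticMICSpec("Aspergillus terreus", "Aspergillus", 0.5, 0.8),
    SyntheticMICSpec("Candida albicans", "Candida", 0.016, 1.0),
    SyntheticMICSpec("Candida dubliniensis", "Candida", 0.016, 1.0),
    SyntheticMICSpec("Candida glabrata", "Candida", 0.25, 1.0),
    SyntheticMICSpec("Candida guilliermondii", "Candida", 0.125, 1.0),
    SyntheticMICSpec("Candida inconspicua", "Candida", 0.25, 1.0),
    SyntheticMICSpec("Candida kefyr", "Candida", 0.016, 1.0),
    SyntheticMICSpec("Candida krusei", "Candida", 0.25, 1.0),
    SyntheticMICSpec("Candida lusitaniae", "Candida", 0.016, 1.0),
    SyntheticMICSpec("Candida metapsilosis", "Candida", 0.031, 1.0),
    SyntheticMICSpec("Candida norvegensis", "Candida", 0.25, 1.0),
    SyntheticMICSpec("Candida orthopsilosis", "Candida", 0.031, 1.0),
    SyntheticMICSpec("Candida parapsilosis", "Candida", 0.031, 1.0),
    SyntheticMICSpec("Candida pelliculosa", "Candida", 0.25, 1.0),
    SyntheticMICSpec("Candida tropicalis", "Candida", 0.063, 1.0),
]


def default_mic_distributions() -> list[MICDistribution]:
    return [generate_mic_distribution(s) for s in DEFAULT_MIC_SPECS]


def load_mic_table(path_or_frame) -> list[MICDistribution]:
    """Load MIC distributions from a tidy CSV (EUCAST-export-like layout)."""
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) \
        else pd.read_csv(path_or_frame)
    _check_schema(df, FIXTURE_SCHEMAS["mic_fixtures"], "mic table")
    return MICDistribution.from_frame(df)


# ---------------------------------------------------------------------------
# closed-form PK curves (oracles for the NCA layer)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPKCurveSpec:
    model: Literal["one_compartment_iv_bolus", "one_compartment_infusion",
                   "biexponential"]
    dose: float                      # mg
    cl: float                        # L/h
    v: float                         # L (central volume)
    k12: float = 0.0                 # 1/h, biexponential only
    k21: float = 0.0
    infusion_h: float = 1.0
    noise_cv: float = 0.0
    times: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 48.0, 97))
    seed: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.cl <= 0 or self.v <= 0 or self.dose <= 0:
            raise ValueError("dose, CL and V must be > 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be increasing")


def _biexponential_constants(spec: SyntheticPKCurveSpec):
    k10 = spec.cl / spec.v
    s = k10 + spec.k12 + spec.k21
    disc = np.sqrt(s * s - 4.0 * k10 * spec.k21)
    alpha, beta = (s + disc) / 2.0, (s - disc) / 2.0
    c0 = spec.dose / spec.v
    a = c0 * (alpha - spec.k21) / (alpha - beta)
    b = c0 * (spec.k21 - beta) / (alpha - beta)
    return a, alpha, b, beta


def generate_pk_curve(spec: SyntheticPKCurveSpec):
    """(times, concentrations, true PKParameters) for a closed-form model."""
    from .nca import PKParameters

    t = spec.times
    k = spec.cl / spec.v
    true = PKParameters(auc_inf=spec.dose / spec.cl)
    if spec.model == "one_compartment_iv_bolus":
        c = spec.dose / spec.v * np.exp(-k * t)
        true.cmax = spec.dose / spec.v
    elif spec.model == "one_compartment_infusion":
        tinf = spec.infusion_h
        rate = spec.dose / tinf
        c = np.where(
            t <= tinf,
            rate / spec.cl * (1.0 - np.exp(-k * t)),
            rate / spec.cl * (1.0 - np.exp(-k * tinf)) * np.exp(-k * (t - tinf)))
        true.cmax = rate / spec.cl * (1.0 - np.exp(-k * tinf))
    elif spec.model == "biexponential":
        if spec.k12 <= 0 or spec.k21 <= 0:
            raise ValueError("biexponential model needs k12, k21 > 0")
        a, alpha, b, beta = _biexponential_constants(spec)
        c = a * np.exp(-alpha * t) + b * np.exp(-beta * t)
        true.cmax = float(c[0])
    else:
        raise ValueError(f"unknown model {spec.model!r}")
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log(1.0 + spec.noise_cv**2))
        c = c * rng.lognormal(0.0, sigma, size=c.shape)
    return t, c, true


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_FILES = {
    "drug_parameters": "drug_parameters.csv",
    "adult_validation": "adult_validation.csv",
    "pediatric_validation": "pediatric_validation.csv",
    "dose_recommendations": "dose_recommendations.csv",
    "mic_fixtures": "mic_synthetic.csv",
}

FIXTURE_SCHEMAS = {
    "drug_parameters": ["parameter", "unit", "value"],
    "adult_validation": ["phenotype", "dose_mg", "schedule", "route",
                         "infusion_min", "male_pct", "age", "parameter",
                         "predicted", "observed", "ratio", "t_last_h",
                         "reference"],
    "pediatric_validation": ["phenotype_mix", "dose_mg_kg", "schedule",
                             "route", "infusion_min", "male_pct", "age_mean",
                             "age_lo", "age_hi", "parameter", "predicted",
                             "observed", "ratio", "reference"],
    "dose_recommendations": ["age_group", "phenotype", "genus", "dose_mg_kg",
                             "cfr_pct"],
    "mic_fixtures": ["species", "genus", "mic_mg_l", "frequency"],
}

#: sha256 of the packaged fixture files, pinned at packaging time
FIXTURE_CHECKSUMS: dict[str, str] = {}


def _check_schema(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing column(s) {missing}")


def load_fixture(name: str, verify_checksum: bool = True) -> pd.DataFrame:
    """Schema-validated packaged table (see FIXTURE_FILES for names)."""
    if name not in FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {sorted(FIXTURE_FILES)}")
    path = resources.files("voripbpk.data").joinpath(FIXTURE_FILES[name])
    raw = path.read_bytes()
    if verify_checksum and name in FIXTURE_CHECKSUMS:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != FIXTURE_CHECKSUMS[name]:
            raise ValueError(f"fixture {name}: checksum mismatch ({digest})")
    from io import BytesIO
    df = pd.read_csv(BytesIO(raw))
    _check_schema(df, FIXTURE_SCHEMAS[name], name)
    return df


def _load_checksums() -> None:
    try:
        path = resources.files("voripbpk.data").joinpath("fixture_checksums.json")
        FIXTURE_CHECKSUMS.update(json.loads(path.read_text()))
    except FileNotFoundError:
        pass


_load_checksums()
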