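"""Structured scenario configuration (YAML/JSON) for the simulation pipeline.

A scenario bundles a virtual population, a dosing regimen and simulation
settings, so that a complete run is reproducible from one file.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .drug import DrugParameters
from .engine import DoseEvent, DosingRegimen, ModelOptions, Route
from .population import PopulationSpec


class RegimenConfig(BaseModel):
    route: Route = "iv_infusion"
    dose: float = Field(..., gt=0)
    unit: str = Field("mg", pattern="^mg(/kg)?$")
    infusion_min: float = Field(0.0, ge=0)
    interval_h: float = Field(12.0, gt=0)
    n_doses: int = Field(1, ge=1)
    start_h: float = 0.0

    def build(self) -> DosingRegimen:
        per_kg = self.unit == "mg/kg"
        events = tuple(
            DoseEvent(self.start_h + i * self.interval_h, self.dose, per_kg,
                      self.infusion_min)
            for i in range(self.n_doses))
        return DosingRegimen(self.route, events)


class ScenarioConfig(BaseModel):
    population: PopulationSpec
    regimen: RegimenConfig
    t_end_h: float = Field(..., gt=0)
    output_dt_h: float = Field(0.25, gt=0)
    rtol: float = 1e-8
    drug: DrugParameters = Field(default_factory=DrugParameters)

    def model_options(self) -> ModelOptions:
        return ModelOptions(rtol=self.rtol)


def load_scenario(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ScenarioConfig.model_validate(data)
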