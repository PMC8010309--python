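"""Whole-body PBPK ODE system for voriconazole.

Perfusion-limited organ compartments in parallel between arterial and venous
blood, with the lung in series carrying the full cardiac output.  The venous
outflow of gut wall, stomach, pancreas and spleen forms the portal vein into
the liver.  Hepatic metabolism follows Michaelis-Menten kinetics on the
unbound liver-water concentration for CYP2C19, CYP3A4 and CYP2C9; active
CYP3A4 is a dynamic state subject to mechanism-based inactivation
(dE/dt = kdeg*E0 - (kdeg + kinact*I/(KI+I))*E), tracked separately for liver
and gut wall; the inactivating exposure I(t) is by default the unbound
concentration in whole tissue (fu*C_tissue, the intracellular-exposure
convention), configurable to the unbound tissue-water concentration.  Renal elimination
is glomerular filtration of unbound drug from arterial plasma.  Oral doses
dissolve in the gut lumen following a Weibull profile and are absorbed into
the gut wall with a permeability-limited first-order rate.

Units: amounts umol, concentrations umol/L, time h (rate constants given
per minute are converted internally); doses enter in mg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .drug import (ADULT_ENZYME_REFERENCE, DrugParameters, EnzymeKinetics,
                   TDIParameters, default_kinetics, partition_coefficients)
from .population import ORGANS, PORTAL_ORGANS, IndividualPhysiology

LN2 = math.log(2.0)

Route = Literal["iv_infusion", "oral_tablet", "oral_capsule", "oral_generic"]
ORAL_ROUTES = ("oral_tablet", "oral_capsule", "oral_generic")


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# elementary kinetic laws (stand-alone, per-minute units as tabulated)
# ---------------------------------------------------------------------------

def tdi_rate(e_cat: float, inhibitor_conc: float, p: TDIParameters) -> float:
    """dE_cat/dt (umol/L/min) of mechanism-based enzyme inactivation."""
    if e_cat < 0 or inhibitor_conc < 0:
        raise ValueError("enzyme and inhibitor concentrations must be >= 0")
    kobs = p.kinact * inhibitor_conc / (p.ki + inhibitor_conc)
    return p.kdeg * p.e0 - (p.kdeg + kobs) * e_cat


def michaelis_menten_rate(cu_liver: float, e_conc: float, k: EnzymeKinetics,
                          v_liver: float) -> float:
    """Metabolic rate (umol/min) at unbound liver-water concentration cu."""
    if cu_liver < 0 or e_conc < 0 or v_liver < 0:
        raise ValueError("inputs must be >= 0")
    return k.kcat * e_conc * v_liver * cu_liver / (k.km + cu_liver)


def weibull_dissolution_fraction(t_min: float | np.ndarray, dt50_min: float,
                                 shape: float) -> float | np.ndarray:
    """Fraction of an oral dose dissolved after t minutes; f(dt50) = 1/2."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    f = 1.0 - np.exp(-LN2 * (t / dt50_min) ** shape)
    return float(f) if f.ndim == 0 else f


# ---------------------------------------------------------------------------
# dosing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseEvent:
    time_h: float
    dose: float                  # mg, or mg/kg when per_kg
    per_kg: bool = False
    infusion_min: float = 0.0    # 0 = bolus (i.v. only)

    def __post_init__(self):
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if self.infusion_min < 0:
            raise ValueError("infusion duration must be >= 0")


@dataclass(frozen=True)
class DosingRegimen:
    route: Route
    events: tuple[DoseEvent, ...]

    def __post_init__(self):
        times = [e.time_h for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose events must be sorted by time")

    @classmethod
    def single_iv(cls, dose: float, infusion_min: float = 60.0,
                  per_kg: bool = False, start_h: float = 0.0) -> "DosingRegimen":
        return cls("iv_infusion",
                   (DoseEvent(start_h, dose, per_kg, infusion_min),))

    @classmethod
    def schedule(cls, dose: float, interval_h: float, n_doses: int,
                 route: Route = "iv_infusion", infusion_min: float = 0.0,
                 per_kg: bool = False, start_h: float = 0.0) -> "DosingRegimen":
        ev = tuple(DoseEvent(start_h + i * interval_h, dose, per_kg, infusion_min)
                   for i in range(n_doses))
        return cls(route, ev)

    @classmethod
    def pediatric_iv_bid(cls, loading_mg_kg: float, maintenance_mg_kg: float,
                         n_days: int = 7, loading_infusion_min: float = 180.0,
                         maintenance_infusion_min: float = 160.0) -> "DosingRegimen":
        """Loading b.i.d. on day 1, maintenance b.i.d. on days 2..n_days."""
        ev = [DoseEvent(0.0, loading_mg_kg, True, loading_infusion_min),
              DoseEvent(12.0, loading_mg_kg, True, loading_infusion_min)]
        for i in range(2, 2 * n_days):
            ev.append(DoseEvent(12.0 * i, maintenance_mg_kg, True,
                                maintenance_infusion_min))
        return cls("iv_infusion", tuple(ev))

    def end_of_dosing_h(self) -> float:
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.time_h + last.infusion_min / 60.0


# ---------------------------------------------------------------------------
# model assembly and integration
# ---------------------------------------------------------------------------

@dataclass
class ModelOptions:
    rtol: float = 1e-8
    atol: float = 1e-9
    gut_cyp3a4_fraction: float = 0.01   # of hepatic molar CYP3A4 content
    enable_tdi: bool = True
    #: concentration driving enzyme inactivation: the unbound concentration in
    #: whole tissue ("tissue_unbound", fu*C_t, the intracellular-exposure
    #: convention) or in tissue water ("water_unbound", fu*C_t/Kp, identical
    #: to the concentration driving metabolism)
    tdi_driving: Literal["tissue_unbound", "water_unbound"] = "tissue_unbound"
    method: str = "LSODA"


# state layout
_N_ORGANS = len(ORGANS)
_I_ART = _N_ORGANS            # 14
_I_VEN = _N_ORGANS + 1        # 15
_I_DISS = _N_ORGANS + 2       # dissolved amount in gut lumen
_I_ELIV = _N_ORGANS + 3       # active CYP3A4, liver (umol/L)
_I_EGUT = _N_ORGANS + 4       # active CYP3A4, gut wall (umol/L)
_I_CUM = _N_ORGANS + 5        # 5 cumulative amounts follow
_N_STATE = _I_CUM + 5
CUMULATIVE_NAMES = ("met_cyp2c19", "met_cyp3a4_liver", "met_cyp3a4_gut",
                    "met_cyp2c9", "renal")


@dataclass
class SimulationResult:
    """Time course of one simulated subject."""

    t: np.ndarray                      # h
    conc_umol_l: np.ndarray            # venous plasma
    conc_mg_l: np.ndarray
    amounts: np.ndarray                # (n_t, 16) umol: ORGANS + art + ven
    compartment_names: list[str]
    lumen_dissolved: np.ndarray        # umol
    lumen_undissolved: np.ndarray      # umol
    enzyme_liver_cyp3a4: np.ndarray    # umol/L
    enzyme_gut_cyp3a4: np.ndarray      # umol/L
    cumulative: dict[str, np.ndarray]  # umol
    administered: np.ndarray           # umol actually delivered up to t
    dose_total_umol: float
    dose_total_mg: float
    body_weight: float
    individual: IndividualPhysiology | None = None
    regimen: DosingRegimen | None = None

    def mass_balance_error(self) -> float:
        """Max relative deviation of the material balance from the given dose."""
        total = (self.amounts.sum(axis=1) + self.lumen_dissolved
                 + self.lumen_undissolved
                 + sum(self.cumulative.values()))
        scale = self.dose_total_umol if self.dose_total_umol > 0 else 1.0
        return float(np.max(np.abs(total - self.administered)) / scale)

    def to_frame(self, subject_id: int | None = None):
        import pandas as pd
        df = pd.DataFrame({"time_h": self.t, "conc_mg_l": self.conc_mg_l})
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df


class PBPKModel:
    """Whole-body model bound to one individual and one parameter set."""

    def __init__(self, individual: IndividualPhysiology,
                 drug: DrugParameters | None = None,
                 kinetics: dict[str, EnzymeKinetics] | None = None,
                 tdi: TDIParameters | None | Literal["default"] = "default",
                 kp_map: dict[str, float] | None = None,
                 options: ModelOptions | None = None):
        self.individual = individual
        self.drug = drug or DrugParameters()
        self.kinetics = default_kinetics() if kinetics is None else kinetics
        self.options = options or ModelOptions()
        if kp_map is None:
            kp_map = partition_coefficients(self.drug)
        missing = [o for o in ORGANS if o not in kp_map]
        if missing:
            raise ValueError(f"partition coefficients missing for organs: {missing}")
        self.kp_map = kp_map

        ind = individual
        self._V = np.array([ind.organ_volumes[o] for o in ORGANS])
        self._Q = np.array([ind.blood_flows[o] for o in ORGANS])
        self._kp = np.array([kp_map[o] for o in ORGANS])
        self._v_art = ind.organ_volumes["arterial_blood"]
        self._v_ven = ind.organ_volumes["venous_blood"]
        self._co = ind.cardiac_output

        self._i_lung = ORGANS.index("lung")
        self._i_liver = ORGANS.index("liver")
        self._i_gut = ORGANS.index("gut_wall")
        self._portal = np.array([ORGANS.index(o) for o in PORTAL_ORGANS])
        self._systemic = np.array([i for i, o in enumerate(ORGANS)
                                   if o not in PORTAL_ORGANS
                                   and i not in (self._i_lung, self._i_liver)])
        self._q_liver_out = self._Q[self._i_liver] + self._Q[self._portal].sum()

        e3a4 = ind.enzyme_liver_conc.get("CYP3A4", 0.0)
        self._e0_liver = e3a4
        v_liv, v_gut = self._V[self._i_liver], self._V[self._i_gut]
        self._e0_gut = (self.options.gut_cyp3a4_fraction * e3a4 * v_liv / v_gut)
        self._e_static = {e: ind.enzyme_liver_conc.get(e, 0.0)
                          for e in ("CYP2C19", "CYP2C9")}
        if tdi == "default":
            tdi = TDIParameters(e0=e3a4)
        elif tdi is not None:
            tdi = replace(tdi, e0=e3a4)
        self.tdi = tdi

        fu = self.drug.fu_plasma
        self._fu = fu
        self._gfr_lh = ind.gfr * 60.0 / 1000.0 * self.drug.gfr_fraction
        # per-hour kinetic constants
        self._kin = {e: (k.km, k.kcat * 60.0) for e, k in self.kinetics.items()}
        self._ka = (self.drug.intestinal_permeability_cm_s * 3600.0
                    * ind.si_surface_cm2 / (ind.si_lumen_l * 1000.0))

    # -- right-hand side -----------------------------------------------------

    def _rhs(self, t, y, infusion_rate, oral_doses):
        V, Q, kp = self._V, self._Q, self._kp
        out = np.zeros(_N_STATE)
        c_out = y[:_N_ORGANS] / V / kp          # venous-equilibrium plasma conc
        c_art = y[_I_ART] / self._v_art
        c_ven = y[_I_VEN] / self._v_ven

        il, ig, ilu = self._i_liver, self._i_gut, self._i_lung
        # perfusion
        d_org = Q * (c_art - c_out)
        d_org[ilu] = self._co * (c_ven - c_out[ilu])
        d_org[il] = (Q[il] * c_art
                     + (Q[self._portal] * c_out[self._portal]).sum()
                     - self._q_liver_out * c_out[il])
        out[:_N_ORGANS] = d_org
        renal = self._gfr_lh * self._fu * max(c_art, 0.0)
        out[_I_ART] = self._co * (c_out[ilu] - c_art) - renal
        out[_I_VEN] = ((Q[self._systemic] * c_out[self._systemic]).sum()
                       + self._q_liver_out * c_out[il]
                       - self._co * c_ven + infusion_rate)
        out[_I_CUM + 4] = renal

        # hepatic metabolism on unbound liver-water concentration
        cu = max(self._fu * c_out[il], 0.0)
        v_liv = V[il]
        for slot, enz in ((0, "CYP2C19"), (3, "CYP2C9")):
            if enz in self._kin:
                km, kcat_h = self._kin[enz]
                rate = kcat_h * self._e_static[enz] * v_liv * cu / (km + cu)
                out[il] -= rate
                out[_I_CUM + (0 if enz == "CYP2C19" else 3)] = rate
        if "CYP3A4" in self._kin:
            km, kcat_h = self._kin["CYP3A4"]
            e_liv = y[_I_ELIV] if self.tdi is not None else self._e0_liver
            rate = kcat_h * e_liv * v_liv * cu / (km + cu)
            out[il] -= rate
            out[_I_CUM + 1] = rate
            # gut wall first-pass metabolism
            cu_g = max(self._fu * c_out[ig], 0.0)
            e_gut = y[_I_EGUT] if self.tdi is not None else self._e0_gut
            rate_g = kcat_h * e_gut * V[ig] * cu_g / (km + cu_g)
            out[ig] -= rate_g
            out[_I_CUM + 2] = rate_g
            if self.tdi is not None and self.options.enable_tdi:
                p = self.tdi
                if self.options.tdi_driving == "tissue_unbound":
                    i_liv, i_gut = cu * kp[il], cu_g * kp[ig]
                else:
                    i_liv, i_gut = cu, cu_g
                kobs = p.kinact * i_liv / (p.ki + i_liv)
                out[_I_ELIV] = 60.0 * (p.kdeg * self._e0_liver
                                       - (p.kdeg + kobs) * y[_I_ELIV])
                kobs_g = p.kinact * i_gut / (p.ki + i_gut)
                out[_I_EGUT] = 60.0 * (p.kdeg * self._e0_gut
                                       - (p.kdeg + kobs_g) * y[_I_EGUT])

        # oral absorption
        if oral_doses is not None:
            diss_in = 0.0
            dt50_h = self.drug.formulation.dt50_min / 60.0
            shape = self.drug.formulation.weibull_shape
            for t0, amt in oral_doses:
                tau = t - t0
                if tau <= 0:
                    continue
                x = tau / dt50_h
                diss_in += amt * LN2 * shape / dt50_h * x ** (shape - 1.0) \
                    * math.exp(-LN2 * x ** shape)
            absorbed = self._ka * max(y[_I_DISS], 0.0)
            out[_I_DISS] = diss_in - absorbed
            out[ig] += absorbed
        return out

    # -- simulation ----------------------------------------------------------

    def _resolve_events(self, regimen: DosingRegimen):
        umol_per_mg = 1000.0 / self.drug.molecular_weight
        resolved = []
        for ev in regimen.events:
            mg = ev.dose * (self.individual.body_weight if ev.per_kg else 1.0)
            resolved.append((ev.time_h, mg * umol_per_mg, ev.infusion_min / 60.0))
        return resolved

    def simulate(self, regimen: DosingRegimen, t_end: float,
                 output_dt: float = 0.1, rtol: float | None = None,
                 atol: float | None = None) -> SimulationResult:
        """Integrate the model over [0, t_end] h with event-aligned restarts."""
        if t_end < regimen.end_of_dosing_h():
            raise ValueError("t_end does not cover the dosing regimen")
        rtol = self.options.rtol if rtol is None else rtol
        atol = self.options.atol if atol is None else atol
        events = self._resolve_events(regimen)
        oral = regimen.route in ORAL_ROUTES

        boundaries = {0.0, float(t_end)}
        for t0, _, dur in events:
            boundaries.add(t0)
            if not oral and dur > 0:
                boundaries.add(min(t0 + dur, t_end))
        bounds = sorted(b for b in boundaries if 0.0 <= b <= t_end)

        y = np.zeros(_N_STATE)
        y[_I_ELIV] = self._e0_liver      # stays at baseline when TDI disabled
        y[_I_EGUT] = self._e0_gut

        ts, ys = [np.array([0.0])], [y.copy()[None, :]]
        oral_given: list[tuple[float, float]] = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            # instantaneous inputs at segment start
            for t0, amt, dur in events:
                if abs(t0 - a) < 1e-12:
                    if oral:
                        oral_given.append((t0, amt))
                    elif dur == 0.0:
                        y[_I_VEN] += amt
            inf_rate = 0.0
            if not oral:
                for t0, amt, dur in events:
                    if dur > 0 and t0 - 1e-12 <= a and b <= t0 + dur + 1e-12:
                        inf_rate += amt / dur
            if b - a < 1e-12:
                continue
            grid = np.arange(math.ceil(a / output_dt) * output_dt, b, output_dt)
            t_eval = np.unique(np.concatenate([grid, [a, b]]))
            t_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
            sol = solve_ivp(self._rhs, (a, b), y, t_eval=t_eval,
                            args=(inf_rate, tuple(oral_given) if oral else None),
                            method=self.options.method, rtol=rtol, atol=atol)
            if not sol.success:
                raise SimulationError(
                    f"integration failed on [{a}, {b}] h: {sol.message}; "
                    f"state={y.tolist()}")
            y = sol.y[:, -1].copy()
            ts.append(sol.t[1:])
            ys.append(sol.y.T[1:])

        t = np.concatenate(ts)
        ymat = np.vstack(ys)
        amounts = ymat[:, : _N_ORGANS + 2]
        conc_um = np.clip(ymat[:, _I_VEN] / self._v_ven, 0.0, None)

        dose_total = sum(amt for _, amt, _ in events)
        administered = np.zeros_like(t)
        # instantaneous inputs are counted just after their instant: the
        # recorded state at the dose time itself is the pre-dose state
        for t0, amt, dur in events:
            if oral or dur == 0.0:
                administered += amt * (t > t0 + 1e-12)
            else:
                administered += amt * np.clip((t - t0) / dur, 0.0, 1.0)
        undissolved = np.zeros_like(t)
        if oral:
            f = self.drug.formulation
            for t0, amt, _ in events:
                tau = np.clip(t - t0, 0.0, None)
                undissolved += amt * np.where(
                    t > t0 + 1e-12,
                    1.0 - weibull_dissolution_fraction(tau * 60.0, f.dt50_min,
                                                       f.weibull_shape),
                    0.0)

        return SimulationResult(
            t=t,
            conc_umol_l=conc_um,
            conc_mg_l=conc_um * self.drug.mg_per_umol,
            amounts=amounts,
            compartment_names=ORGANS + ["arterial_blood", "venous_blood"],
            lumen_dissolved=np.clip(ymat[:, _I_DISS], 0.0, None),
            lumen_undissolved=undissolved,
            enzyme_liver_cyp3a4=ymat[:, _I_ELIV],
            enzyme_gut_cyp3a4=ymat[:, _I_EGUT],
            cumulative={n: ymat[:, _I_CUM + i]
                        for i, n in enumerate(CUMULATIVE_NAMES)},
            administered=administered,
            dose_total_umol=dose_total,
            dose_total_mg=dose_total * self.drug.mg_per_umol,
            body_weight=self.individual.body_weight,
            individual=self.individual,
            regimen=regimen,
        )


def build_model(individual: IndividualPhysiology,
                drug: DrugParameters | None = None,
                kinetics: dict[str, EnzymeKinetics] | None = None,
                tdi: TDIParameters | None | Literal["default"] = "default",
                kp_map: dict[str, float] | None = None,
                options: ModelOptions | None = None) -> PBPKModel:
    """Assemble the whole-body ODE system for one individual."""
    return PBPKModel(individual, drug, kinetics, tdi, kp_map, options)


def simulate_population(population: Sequence[IndividualPhysiology],
                        regimen: DosingRegimen, t_end: float,
                        drug: DrugParameters | None = None,
                        kinetics: dict[str, EnzymeKinetics] | None = None,
                        tdi: TDIParameters | None | Literal["default"] = "default",
                        options: ModelOptions | None = None,
                        output_dt: float = 0.1) -> list[SimulationResult]:
    """Independent per-subject simulations (order-stable)."""
    drug = drug or DrugParameters()
    kp = partition_coefficients(drug)
    results = []
    for i, ind in enumerate(population):
        try:
            model = PBPKModel(ind, drug, kinetics, tdi, kp, options)
            results.append(model.simulate(regimen, t_end, output_dt=output_dt))
        except Exception as exc:
            raise SimulationError(f"subject {i} failed: {exc}") from exc
    return results
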