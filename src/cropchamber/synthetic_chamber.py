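"""Forward simulator of a gas-tight cultivation chamber with a growing crop.

The simulated facility mirrors a closed plant-characterisation chamber: a
fixed 4.9 m^3 atmosphere over a 1.8 m^2 hydroponic cultivation area, a
16/8 h photoperiod at 26/20 degC day/night, CO2 held at a 1000 ppmv daytime
floor by pure-CO2 injection, a small first-order wall leak, and a single
scheduled venting event to keep O2 below its safety threshold.  The canopy
follows logistic growth in projected leaf area index (PLAI); net O2
production scales with projected leaf area during the day, and a fixed
fraction of the daytime flux is respired at night.  Nitrogen is drawn from
the nutrient solution in proportion to biomass gain, preferentially from
NH4+, while stock dosing holds NO3- at its setpoint.

Every flux is tallied into a ground-truth ledger so that downstream
estimators (leak rate, daily O2 production, growth rate, N mass balance)
can be validated against exact mole conservation without any real data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canopy_growth import PLAISeries
from .errors import DepletedIonError, ValidationError
from .gas_exchange import AMBIENT_CO2_PPMV, AMBIENT_O2_PCT, R_GAS
from .nutrient_balance import ION_FIELDS, SolutionState

# ---------------------------------------------------------------------------
# Configuration

@dataclass
class NoiseSD:
    """Per-channel Gaussian sensor-noise standard deviations."""

    o2_pct: float = 0.002      # vol-%
    co2_ppmv: float = 2.0
    pressure_pa: float = 10.0
    temp_k: float = 0.02
    plai_frac: float = 0.025   # multiplicative, from segmentation uncertainty

    @classmethod
    def off(cls) -> "NoiseSD":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    @property
    def any(self) -> bool:
        return (
            max(
                self.o2_pct,
                self.co2_ppmv,
                self.pressure_pa,
                self.temp_k,
                self.plai_frac,
            )
            > 0
        )


@dataclass
class ChamberConfig:
    """Physical chamber, environment control, and sensor parameters."""

    volume: float = 4.9               # gas volume, m^3
    cultivation_area: float = 1.8     # m^2
    pressure0: float = 101325.0       # initial pressure, Pa
    day_length: float = 16.0          # photoperiod, h
    temp_day: float = 299.15          # K (26 degC)
    temp_night: float = 293.15        # K (20 degC)
    co2_setpoint: float = 1000.0      # daytime CO2 floor, ppmv
    o2_vent_threshold: float = 25.0   # vol-% triggering an unscheduled vent
    vent_day: int | None = 19         # DAT of the scheduled venting (None: never)
    leak_rate: float = 8.2e-4         # fractional gas loss, h^-1
    noise_sd: NoiseSD = field(default_factory=NoiseSD)
    step: float = 1.0                 # integration step, h

    def __post_init__(self):
        if self.volume <= 0 or self.cultivation_area <= 0:
            raise ValidationError("volume and cultivation_area must be positive")
        if not 0 < self.day_length < 24:
            raise ValidationError("day length must be in (0, 24) h")
        if self.leak_rate < 0:
            raise ValidationError("leak_rate must be >= 0")
        if self.step <= 0 or abs(24.0 / self.step - round(24.0 / self.step)) > 1e-9:
            raise ValidationError("step must be positive and divide 24 h")


@dataclass
class CropParams:
    """Crop behaviour: canopy expansion, gas fluxes, and nitrogen demand."""

    plai0: float = 0.010       # PLAI at 2 DAT, m^2 m^-2
    mu: float = 0.22           # specific growth rate, d^-1
    plai_max: float = 0.75     # logistic ceiling, m^2 m^-2
    p_spec: float = 1.25       # daytime O2 production per PLA, mol d^-1 m^-2
    resp_frac: float = 0.15    # night respiration as fraction of daytime flux
    pq: float = 1.0            # photosynthetic quotient, mol O2 per mol CO2
    n_demand: float = 3.1      # N uptake per biomass gain, mol kg^-1 DW
    nh4_pref: float = 0.31     # fraction of N uptake drawn from NH4+ while available
    dw_per_area: float = 0.27  # shoot DW per projected leaf area, kg m^-2

    def __post_init__(self):
        if self.plai0 <= 0 or self.plai_max < self.plai0:
            raise ValidationError("need 0 < plai0 <= plai_max")
        if not 0 <= self.nh4_pref <= 1:
            raise ValidationError("nh4_pref must be in [0, 1]")
        if self.pq <= 0:
            raise ValidationError("pq must be positive")
        for name in ("mu", "p_spec", "resp_frac", "n_demand", "dw_per_area"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Atmosphere state and elementary updates

@dataclass
class AtmosphereState:
    """Mole inventory of the chamber gas at a given temperature.

    Pressure is always derived from total moles through the ideal gas law;
    it is never stored independently.
    """

    n_o2: float
    n_co2: float
    n_inert: float
    temperature: float
    volume: float

    def __post_init__(self):
        if min(self.n_o2, self.n_co2, self.n_inert) < 0:
            raise ValidationError("mole amounts must be >= 0")
        if self.temperature <= 0 or self.volume <= 0:
            raise ValidationError("temperature and volume must be positive")

    @property
    def n_total(self) -> float:
        return self.n_o2 + self.n_co2 + self.n_inert

    @property
    def pressure(self) -> float:
        return self.n_total * R_GAS * self.temperature / self.volume

    @property
    def o2_pct(self) -> float:
        return 100.0 * self.n_o2 / self.n_total

    @property
    def co2_ppmv(self) -> float:
        return 1e6 * self.n_co2 / self.n_total

    @classmethod
    def ambient(
        cls, pressure: float, temperature: float, volume: float
    ) -> "AtmosphereState":
        """Chamber freshly equilibrated with outside air."""
        n = pressure * volume / (R_GAS * temperature)
        n_o2 = n * AMBIENT_O2_PCT / 100.0
        n_co2 = n * AMBIENT_CO2_PPMV * 1e-6
        return cls(n_o2, n_co2, n - n_o2 - n_co2, temperature, volume)


def step_atmosphere(
    state: AtmosphereState,
    fluxes: dict[str, float],
    leak_rate: float,
    dt: float,
) -> tuple[AtmosphereState, dict[str, float]]:
    """Advance the atmosphere by one step: apply fluxes, then the leak.

    ``fluxes`` maps species (``o2``, ``co2``, ``inert``) to mole changes
    over ``dt`` hours (biological exchange plus injections).  Every species
    is then multiplied by the survival factor ``1 - leak_rate * dt``.
    Returns the new state and the per-species moles lost to the leak.
    A flux that would drive a species negative is an error.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    survival = 1.0 - leak_rate * dt
    if survival <= 0:
        raise ValidationError("leak_rate * dt >= 1: step too large for this leak")
    n = {
        "o2": state.n_o2 + fluxes.get("o2", 0.0),
        "co2": state.n_co2 + fluxes.get("co2", 0.0),
        "inert": state.n_inert + fluxes.get("inert", 0.0),
    }
    for sp, val in n.items():
        if val < 0:
            raise ValidationError(
                f"flux drives {sp} negative ({val:.4g} mol) within one step"
            )
    losses = {sp: val * leak_rate * dt for sp, val in n.items()}
    new = AtmosphereState(
        n_o2=n["o2"] * survival,
        n_co2=n["co2"] * survival,
        n_inert=n["inert"] * survival,
        temperature=state.temperature,
        volume=state.volume,
    )
    return new, losses


def co2_controller(state: AtmosphereState, setpoint: float, is_day: bool) -> float:
    """Moles of pure CO2 to inject to restore the daytime setpoint.

    Returns the concentration deficit converted to moles
    (``(setpoint - ppmv) * 1e-6 * n_total``) during the day phase, and 0 at
    night (respiration is allowed to raise CO2) or when at/above setpoint.
    """
    if setpoint <= 0:
        raise ValidationError("setpoint must be positive")
    if not is_day:
        return 0.0
    deficit_ppmv = setpoint - state.co2_ppmv
    if deficit_ppmv <= 0:
        return 0.0
    return deficit_ppmv * 1e-6 * state.n_total


def vent_chamber(state: AtmosphereState) -> tuple[AtmosphereState, dict[str, float]]:
    """Instantaneous vent: mole fractions reset to ambient at constant pressure.

    Total moles are preserved (the chamber re-equalises with outside air);
    O2 and CO2 surpluses are flushed out while inert gas flows in.  Returns
    the new state and the net moles lost per species (inert is negative).
    """
    n = state.n_total
    new = AtmosphereState(
        n_o2=n * AMBIENT_O2_PCT / 100.0,
        n_co2=n * AMBIENT_CO2_PPMV * 1e-6,
        n_inert=n * (1.0 - AMBIENT_O2_PCT / 100.0 - AMBIENT_CO2_PPMV * 1e-6),
        temperature=state.temperature,
        volume=state.volume,
    )
    losses = {
        "o2": state.n_o2 - new.n_o2,
        "co2": state.n_co2 - new.n_co2,
        "inert": state.n_inert - new.n_inert,
    }
    return new, losses


def grow_canopy(plai: float, crop: CropParams, dt: float) -> float:
    """Logistic canopy update over ``dt`` days (closed-form, exact).

    d(PLAI)/dt = mu * PLAI * (1 - PLAI / plai_max); for PLAI much smaller
    than the ceiling this is exponential growth at rate ``mu``.
    """
    if plai < 0:
        raise ValidationError("plai must be >= 0")
    if crop.mu == 0 or plai == 0:
        return plai
    pm = crop.plai_max
    if not np.isfinite(pm):
        return plai * np.exp(crop.mu * dt)
    if plai >= pm:
        return plai
    return pm / (1.0 + (pm / plai - 1.0) * np.exp(-crop.mu * dt))


def uptake_nitrogen(
    solution: SolutionState,
    d_biomass: float,
    crop: CropParams,
    no3_setpoint: float,
    stock_nh4_n_ratio: float,
) -> tuple[SolutionState, dict[str, float]]:
    """Draw N for a biomass increment, then dose stock to restore NO3-.

    Removes ``n_demand * d_biomass`` mol N, taking the fraction ``nh4_pref``
    from NH4+ (falling back to NO3- once NH4+ is exhausted).  Stock feeding
    then restores the NO3- concentration to its setpoint exactly; the stock
    carries NH4+ at ``stock_nh4_n_ratio`` of its total N, so the NH4+ added
    is ``rho / (1 - rho)`` times the NO3- added.  Base addition (mole per
    mole of NH4+ taken up, the proton-balance signature of ammonium
    nutrition) is logged alongside.
    """
    if d_biomass < 0:
        raise ValidationError("d_biomass must be >= 0")
    if not 0 <= stock_nh4_n_ratio < 1:
        raise ValidationError("stock NH4:N ratio must be in [0, 1)")
    log = {
        "n_from_nh4_mol": 0.0,
        "n_from_no3_mol": 0.0,
        "no3_added_mol": 0.0,
        "nh4_added_mol": 0.0,
        "base_added_mol": 0.0,
    }
    if d_biomass == 0:
        return solution, log
    demand = crop.n_demand * d_biomass  # mol N
    inv_nh4 = solution.inventory("nh4")
    inv_no3 = solution.inventory("no3")
    if demand > inv_nh4 + inv_no3 + 1e-15:
        ion = "NH4+" if inv_nh4 < inv_no3 else "NO3-"
        raise DepletedIonError(ion, demand, inv_nh4 + inv_no3)
    from_nh4 = min(crop.nh4_pref * demand, inv_nh4)
    from_no3 = demand - from_nh4
    if from_no3 > inv_no3 + 1e-15:
        raise DepletedIonError("NO3-", from_no3, inv_no3)
    v = solution.volume_l
    nh4_mm = (inv_nh4 - from_nh4) / v * 1e3
    no3_mm = (inv_no3 - from_no3) / v * 1e3
    # stock dosing: restore NO3- to setpoint, NH4+ rides along at the stock ratio
    no3_add = max(0.0, (no3_setpoint - no3_mm) * v * 1e-3)
    nh4_add = (
        no3_add * stock_nh4_n_ratio / (1.0 - stock_nh4_n_ratio) if no3_add > 0 else 0.0
    )
    no3_mm += no3_add / v * 1e3
    nh4_mm += nh4_add / v * 1e3
    log.update(
        n_from_nh4_mol=from_nh4,
        n_from_no3_mol=from_no3,
        no3_added_mol=no3_add,
        nh4_added_mol=nh4_add,
        base_added_mol=from_nh4,
    )
    new = dataclasses.replace(solution, nh4=nh4_mm, no3=no3_mm)
    return new, log


# ---------------------------------------------------------------------------
# Whole-test simulation

@dataclass
class SimOutput:
    """Complete synthetic crop test: datasets plus the ground-truth ledger."""

    sensor: pd.DataFrame       # hourly chamber sensor rows
    plai: PLAISeries           # 2-day PLAI samples
    solution: pd.DataFrame     # 2-day nutrient-solution samples
    dosing: pd.DataFrame       # timestamped stock/base/CO2 additions
    harvest: pd.DataFrame      # per-plant harvest records
    truth: dict                # exact daily fluxes and cumulative budgets


def default_solution(kind: str = "lo_nh4", volume_l: float = 270.0) -> SolutionState:
    """Start-of-test nutrient solutions for the two study scenarios.

    ``lo_nh4``: 9.7 mM NO3-, 1.3 mM NH4+ (NH4:N 0.12); ``hi_nh4``: 5.6 mM
    NO3-, 5.3 mM NH4+ (NH4:N 0.49); both 11 mM total N at start.
    """
    common = dict(dat=0.0, volume_l=volume_l, no2=0.0, mg=0.7, po4=0.8, ph=5.9)
    if kind == "lo_nh4":
        return SolutionState(
            no3=9.7, nh4=1.3, k=3.7, ca=4.6, na=5.1, cl=4.5, so4=0.8, ec=1.9, **common
        )
    if kind == "hi_nh4":
        return SolutionState(
            no3=5.6, nh4=5.3, k=3.5, ca=4.8, na=4.9, cl=4.7, so4=4.9, ec=2.2, **common
        )
    raise ValidationError(f"unknown solution kind {kind!r}")


def scenario(kind: str = "lo_nh4") -> tuple[ChamberConfig, CropParams, SolutionState]:
    """Chamber, crop and solution for the two study scenarios.

    ``lo_nh4``: mostly-nitrate nutrition — faster canopy expansion
    (mu = 0.22 d^-1, ceiling 0.75) with a moderate ammonium uptake
    preference.  ``hi_nh4``: half the N supplied as NH4+ — slower expansion
    (mu = 0.18 d^-1, ceiling 0.42), marginally higher per-area productivity,
    and N drawn from NH4+ exclusively while it lasts.
    """
    if kind == "lo_nh4":
        crop = CropParams(mu=0.22, plai_max=0.75, p_spec=1.25, nh4_pref=0.31)
    elif kind == "hi_nh4":
        crop = CropParams(mu=0.18, plai_max=0.42, p_spec=1.30, nh4_pref=1.0)
    else:
        raise ValidationError(f"unknown scenario {kind!r}")
    return ChamberConfig(), crop, default_solution(kind)


def sample_harvest(
    total_shoot_dw_kg: float,
    n_plants: int = 18,
    seed: int = 0,
    dw_content: float = 0.07,
    root_shoot: float = 0.14,
    leaf_area_per_dw_cm2_g: float = 205.0,
    cv: float = 0.25,
) -> pd.DataFrame:
    """Split a crop's shoot dry weight into per-plant harvest records.

    Plant-to-plant variation is multiplicative (gamma weights normalised to
    preserve the crop total exactly).  Fresh weight follows from the
    dry-weight content, root mass from the root:shoot ratio, and leaf area
    from a fixed specific leaf area.  Deterministic per seed.
    """
    if n_plants <= 0:
        raise ValidationError("n_plants must be positive")
    rng = np.random.default_rng(seed)
    shape = 1.0 / cv**2
    w = rng.gamma(shape, 1.0 / shape, size=n_plants)
    w *= n_plants / w.sum()
    shoot_dw_g = total_shoot_dw_kg * 1000.0 / n_plants * w
    root_dw_g = shoot_dw_g * root_shoot * rng.normal(1.0, 0.1, n_plants).clip(0.5)
    shoot_fw_g = shoot_dw_g / dw_content * rng.normal(1.0, 0.05, n_plants).clip(0.5)
    return pd.DataFrame(
        {
            "plant_id": [f"plant_{i + 1:02d}" for i in range(n_plants)],
            "shoot_fw_g": shoot_fw_g,
            "shoot_dw_g": shoot_dw_g,
            "root_dw_g": root_dw_g,
            "leaf_count": np.maximum(1, rng.poisson(36, n_plants)),
            "leaf_area_cm2": shoot_dw_g * leaf_area_per_dw_cm2_g,
            "stem_diameter_mm": rng.normal(17.0, 2.0, n_plants).clip(5.0),
        }
    )


def simulate_crop_test(
    config: ChamberConfig,
    crop: CropParams,
    solution0: SolutionState,
    duration: int = 28,
    seed: int = 0,
    no3_setpoint: float | None = None,
    stock_nh4_n_ratio: float | None = None,
    o2_schedule_mol_per_d: np.ndarray | None = None,
) -> SimOutput:
    """Run a full crop test and return datasets plus the ground-truth ledger.

    Explicit-Euler integration at ``config.step`` hours.  Each day holds one
    full light phase followed by one dark phase; the clock starts at lights-on
    of day 0.  ``o2_schedule_mol_per_d`` overrides the canopy-coupled O2 flux
    with an imposed per-day net schedule (applied during the light phase,
    with night respiration off) — used for validation against arithmetic.

    With all ``noise_sd`` channels at zero the output is deterministic and
    independent of ``seed``.  Ground truth satisfies exact mole conservation:
    per day, Delta(chamber O2) = production - leak loss - vent loss.
    """
    if duration < 2:
        raise ValidationError("duration must be at least 2 days")
    rng = np.random.default_rng(seed)
    dt = config.step
    n_steps = int(round(duration * 24 / dt))
    area = config.cultivation_area

    no3_setpoint = solution0.no3 if no3_setpoint is None else no3_setpoint
    if stock_nh4_n_ratio is None:
        stock_nh4_n_ratio = solution0.nh4 / (solution0.nh4 + solution0.no3)

    state = AtmosphereState.ambient(config.pressure0, config.temp_day, config.volume)
    # anchor the growth curve so that the 2-DAT sample equals plai0
    pm = crop.plai_max
    if np.isfinite(pm):
        plai = pm / (1.0 + (pm / crop.plai0 - 1.0) * np.exp(2.0 * crop.mu))
    else:
        plai = crop.plai0 * np.exp(-2.0 * crop.mu)
    solution = dataclasses.replace(solution0)

    daily = {
        k: np.zeros(duration)
        for k in ("o2_net", "o2_leak", "o2_vent", "co2_injection", "co2_net")
    }
    n_uptake = {"nh4": 0.0, "no3": 0.0}
    n_added = {"nh4": 0.0, "no3": 0.0}
    n_removed_samples = 0.0
    base_added = 0.0
    vent_times: list[float] = []
    vented_scheduled = False

    sensor_rows: list[dict] = []
    solution_rows: list[dict] = []
    dosing_rows: list[dict] = []
    plai_dat: list[float] = []
    plai_vals: list[float] = []

    def is_day_at(t: float) -> bool:
        return (t % 24.0) < config.day_length

    def record_sensor(t: float, event: str) -> None:
        nd = config.noise_sd
        draws = rng.standard_normal(4)
        sensor_rows.append(
            {
                "time_h": t,
                "dat": int(t // 24) if t < duration * 24 else duration - 1,
                "is_day": is_day_at(t),
                "o2_pct": state.o2_pct + nd.o2_pct * draws[0],
                "co2_ppmv": state.co2_ppmv + nd.co2_ppmv * draws[1],
                "pressure_pa": state.pressure + nd.pressure_pa * draws[2],
                "temp_k": state.temperature + nd.temp_k * draws[3],
                "event": event,
            }
        )

    def record_solution(t: float) -> None:
        row = {"dat": t / 24.0, "volume_l": solution.volume_l}
        row.update({ion: getattr(solution, ion) for ion in ION_FIELDS})
        row["ph"] = solution.ph
        solution_rows.append(row)

    def record_plai(t: float) -> None:
        # multiplicative measurement noise, as image segmentation would add
        measured = plai * np.exp(config.noise_sd.plai_frac * rng.standard_normal())
        plai_dat.append(t / 24.0)
        plai_vals.append(min(measured, 1.0))

    record_sensor(0.0, "none")
    record_solution(0.0)
    record_plai(0.0)

    for k in range(n_steps):
        t = k * dt
        day = int(t // 24)
        is_day = is_day_at(t)
        state = dataclasses.replace(
            state, temperature=config.temp_day if is_day else config.temp_night
        )
        pla = plai * area

        # biological gas fluxes over this step
        if o2_schedule_mol_per_d is not None:
            o2_flux = (
                o2_schedule_mol_per_d[day] * dt / config.day_length if is_day else 0.0
            )
        elif is_day:
            o2_flux = crop.p_spec * pla * dt / config.day_length
        else:
            night_length = 24.0 - config.day_length
            o2_flux = -crop.resp_frac * crop.p_spec * pla * dt / night_length
        co2_flux = -o2_flux / crop.pq

        injection = 0.0
        if is_day:
            # controller acts within the step: top the post-drawdown CO2
            # back up to the setpoint (injection and drawdown overlap in
            # time, so the intermediate inventory never underflows)
            n_total_after = state.n_total + o2_flux + co2_flux
            n_co2_after = state.n_co2 + co2_flux
            s_frac = config.co2_setpoint * 1e-6
            # exact restore: (n_co2 + x) / (n_total + x) = setpoint fraction
            injection = max(
                0.0, (s_frac * n_total_after - n_co2_after) / (1.0 - s_frac)
            )
        state, leak_losses = step_atmosphere(
            state,
            {"o2": o2_flux, "co2": co2_flux + injection},
            config.leak_rate,
            dt,
        )
        daily["o2_net"][day] += o2_flux
        daily["co2_net"][day] += co2_flux
        daily["o2_leak"][day] += leak_losses["o2"]
        daily["co2_injection"][day] += injection
        if injection > 0:
            dosing_rows.append(
                {"time_h": t + dt, "kind": "co2", "amount": injection, "unit": "mol"}
            )

        # canopy growth and nitrogen draw
        new_plai = grow_canopy(plai, crop, dt / 24.0)
        d_biomass = crop.dw_per_area * area * (new_plai - plai)
        plai = new_plai
        if d_biomass > 0:
            solution, log = uptake_nitrogen(
                solution, d_biomass, crop, no3_setpoint, stock_nh4_n_ratio
            )
            n_uptake["nh4"] += log["n_from_nh4_mol"]
            n_uptake["no3"] += log["n_from_no3_mol"]
            n_added["nh4"] += log["nh4_added_mol"]
            n_added["no3"] += log["no3_added_mol"]
            base_added += log["base_added_mol"]
            if log["no3_added_mol"] > 0:
                dosing_rows.append(
                    {
                        "time_h": t + dt,
                        "kind": "stock_n",
                        "amount": log["no3_added_mol"] + log["nh4_added_mol"],
                        "unit": "mol",
                    }
                )
            if log["base_added_mol"] > 0:
                dosing_rows.append(
                    {
                        "time_h": t + dt,
                        "kind": "base",
                        "amount": log["base_added_mol"],
                        "unit": "mol",
                    }
                )

        t_next = t + dt
        event = "none"

        # venting: scheduled one hour into the vent day (so neighbouring
        # 24 h leak-estimation windows stay clean), or forced by the O2 cap
        scheduled = (
            config.vent_day is not None
            and not vented_scheduled
            and t_next >= 24.0 * config.vent_day + dt
            and t_next < 24.0 * (config.vent_day + 1)
        )
        if scheduled or state.o2_pct > config.o2_vent_threshold:
            state, vent_losses = vent_chamber(state)
            daily["o2_vent"][int(t_next // 24) if t_next < duration * 24 else day] += (
                vent_losses["o2"]
            )
            vent_times.append(t_next)
            event = "vent"
            if scheduled:
                vented_scheduled = True

        state = dataclasses.replace(
            state,
            temperature=config.temp_day if is_day_at(t_next) else config.temp_night,
        )
        record_sensor(t_next, event)

        # two-day sampling: log PLAI and solution, then remove the 25 mL sample
        if abs(t_next % 48.0) < 1e-9 or abs(t_next % 48.0 - 48.0) < 1e-9:
            record_plai(t_next)
            record_solution(t_next)
            if t_next < duration * 24:
                sample_l = 0.025
                n_removed_samples += solution.total_n_mm * sample_l * 1e-3
                solution = dataclasses.replace(
                    solution,
                    volume_l=solution.volume_l - sample_l,
                    dat=t_next / 24.0,
                )

    total_shoot_dw = crop.dw_per_area * area * plai
    harvest = sample_harvest(
        total_shoot_dw, n_plants=18, seed=int(rng.integers(0, 2**31 - 1))
    )

    truth = {
        "daily_o2_net": daily["o2_net"],
        "daily_o2_leak": daily["o2_leak"],
        "daily_o2_vent": daily["o2_vent"],
        "daily_co2_injection": daily["co2_injection"],
        "leak_rate_per_h": config.leak_rate,
        "n_uptake_nh4_mol": n_uptake["nh4"],
        "n_uptake_no3_mol": n_uptake["no3"],
        "n_added_nh4_mol": n_added["nh4"],
        "n_added_no3_mol": n_added["no3"],
        "n_removed_samples_mol": n_removed_samples,
        "base_added_mol": base_added,
        "solution_n_start_mol": solution0.total_n_mm * solution0.volume_l * 1e-3,
        "solution_n_end_mol": solution.total_n_mm * solution.volume_l * 1e-3,
        "solution_end": solution,
        "final_plai": plai,
        "total_shoot_dw_kg": total_shoot_dw,
        "vent_times_h": vent_times,
    }
    return SimOutput(
        sensor=pd.DataFrame(sensor_rows),
        plai=PLAISeries(
            dat=np.array(plai_dat), plai=np.array(plai_vals), cultivation_area=area
        ),
        solution=pd.DataFrame(solution_rows),
        dosing=pd.DataFrame(dosing_rows, columns=["time_h", "kind", "amount", "unit"]),
        harvest=harvest,
        truth=truth,
    )
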