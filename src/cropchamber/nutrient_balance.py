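"""Hydroponic nutrient-solution bookkeeping and the nitrogen mass balance.

The recirculating solution (~270 L) is sampled every two days; ion
concentrations (mM) times the liquid volume (L) give mole inventories.
Nitrogen enters as NO3- and NH4+ (stock dosing holds NO3- at its setpoint
while NH4+ is free-running), leaves with the crop, and can appear as NO2-
through incidental nitrification.  The mass balance

    consumption = start + net additions - end          [mol N]
    closure     = 100 * biomass N / consumption        [%]

checks how much of the inorganic N drawn from the solution is recovered in
harvested biomass.  The apparent NH4+:N consumption ratio and the ratio
trajectories describe how the solution composition drifts in a closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Ion concentration fields carried by a solution state, all in mM.
ION_FIELDS = ("no3", "nh4", "no2", "k", "ca", "mg", "na", "cl", "so4", "po4")

#: Molar mass of nitrogen, g mol^-1 (for element-mass conversions).
M_N = 14.007


@dataclass
class SolutionState:
    """Nutrient-solution snapshot: ion concentrations (mM) plus volume (L)."""

    dat: float
    volume_l: float
    no3: float
    nh4: float
    no2: float = 0.0
    k: float = 0.0
    ca: float = 0.0
    mg: float = 0.0
    na: float = 0.0
    cl: float = 0.0
    so4: float = 0.0
    po4: float = 0.0
    ph: float = 5.9
    ec: float = float("nan")

    def __post_init__(self):
        if self.volume_l <= 0:
            raise ValidationError("solution volume must be positive")
        for ion in ION_FIELDS:
            if getattr(self, ion) < 0:
                raise ValidationError(f"negative concentration for {ion}")

    @property
    def total_n_mm(self) -> float:
        """Total inorganic N concentration, mM (NO3 + NH4 + NO2)."""
        return self.no3 + self.nh4 + self.no2

    def inventory(self, ion: str) -> float:
        """Mole inventory of one ion: concentration x volume."""
        return ion_inventory(getattr(self, ion), self.volume_l)


def moving_average(values, window: int = 3) -> np.ndarray:
    """Centred moving average with truncated windows at the series ends.

    Used to filter analysis uncertainty out of sampled concentration series.
    ``window`` must be odd; ``window=1`` is the identity.
    """
    values = np.asarray(values, float)
    if window % 2 == 0:
        raise ValidationError(f"moving-average window must be odd, got {window}")
    if window > len(values):
        raise ValidationError(
            f"window {window} longer than series of length {len(values)}"
        )
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def ion_inventory(concentration_mm: float, volume_l: float) -> float:
    """Moles of an ion in the loop: mM x L x 1e-3."""
    if concentration_mm < 0 or volume_l < 0:
        raise ValidationError("concentration and volume must be >= 0")
    return concentration_mm * volume_l * 1e-3


@dataclass
class MassBalanceLedger:
    """Start/addition/end/biomass bookkeeping for inorganic N, all in mol.

    Additions are net of solution samples removed during the test.  NO2- is
    counted in the end inventory (it holds N) but consumption is never
    attributed to it — its appearance is flagged as possible nitrification.
    The optional ``*_total`` fields let a caller supply independently rounded
    totals (as printed tables do); they default to the species sums.
    """

    start_no3: float
    start_nh4: float
    add_no3: float
    add_nh4: float
    end_no3: float
    end_nh4: float
    end_no2: float = 0.0
    biomass_n_shoot: float = 0.0
    biomass_n_root: float = 0.0
    start_total: float | None = None
    add_total: float | None = None
    end_total: float | None = None

    def __post_init__(self):
        for name in (
            "start_no3", "start_nh4", "end_no3", "end_nh4", "end_no2",
            "biomass_n_shoot", "biomass_n_root",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"ledger entry {name} must be >= 0")
        if self.start_total is None:
            self.start_total = self.start_no3 + self.start_nh4
        if self.add_total is None:
            self.add_total = self.add_no3 + self.add_nh4
        if self.end_total is None:
            self.end_total = self.end_no3 + self.end_nh4 + self.end_no2


def n_mass_balance(ledger: MassBalanceLedger) -> dict:
    """Total and species-wise inorganic-N consumption and closure.

    consumption = start + additions - end; closure = 100 x biomass N /
    consumption.  Species-wise consumptions come from the species rows;
    the total uses the ledger's totals (which default to the species sums).
    Closure is reported both unrounded and at the nearest-integer-percent
    reporting convention.
    """
    consumption = ledger.start_total + ledger.add_total - ledger.end_total
    no3_consumed = ledger.start_no3 + ledger.add_no3 - ledger.end_no3
    nh4_consumed = ledger.start_nh4 + ledger.add_nh4 - ledger.end_nh4
    biomass_n = ledger.biomass_n_shoot + ledger.biomass_n_root
    if consumption <= 0 and biomass_n > 0:
        raise ValidationError(
            "non-positive N consumption with non-zero biomass N: ledger inconsistent"
        )
    closure = 100.0 * biomass_n / consumption if consumption > 0 else float("nan")
    return {
        "consumption_mol": consumption,
        "no3_consumed_mol": no3_consumed,
        "nh4_consumed_mol": nh4_consumed,
        "biomass_n_mol": biomass_n,
        "closure_pct": closure,
        "closure_pct_rounded": int(round(closure)) if np.isfinite(closure) else None,
        "nitrification_flag": ledger.end_no2 > 0,
    }


def consumption_ratio(nh4_consumed: float, no3_consumed: float) -> float:
    """Apparent NH4+:N consumption ratio, nh4 / (nh4 + no3) [mol mol^-1].

    Returns NaN for the undefined 0/0 case.
    """
    if nh4_consumed < 0 or no3_consumed < 0:
        raise ValidationError("consumed amounts must be >= 0")
    total = nh4_consumed + no3_consumed
    if total == 0:
        return float("nan")
    return nh4_consumed / total


def ratio_trajectory(states: list[SolutionState] | pd.DataFrame) -> pd.DataFrame:
    """Per-sample molar ratios: NH4:N, NH4:NO3, Na:N, Cl:N, K:N.

    Total N includes NO2-.  A sample with zero total N is an error.
    """
    if isinstance(states, pd.DataFrame):
        df = states
    else:
        df = pd.DataFrame(
            [{f: getattr(s, f) for f in ("dat",) + ION_FIELDS} for s in states]
        )
    total_n = df["no3"] + df["nh4"] + df.get("no2", 0.0)
    if (total_n <= 0).any():
        bad = df["dat"][total_n <= 0].iloc[0]
        raise ValidationError(f"zero total N at DAT {bad}")
    out = pd.DataFrame({"dat": df["dat"]})
    out["nh4_n"] = df["nh4"] / total_n
    out["nh4_no3"] = np.where(df["no3"] > 0, df["nh4"] / df["no3"], np.nan)
    for ion in ("na", "cl", "k"):
        if ion in df:
            out[f"{ion}_n"] = df[ion] / total_n
    return out


def topup_projection(
    end_state: SolutionState, stock_nh4_n_ratio: float, target_total_n_mm: float
) -> float:
    """NH4+:N ratio after topping the end-of-test solution back to target N.

    Stock is added with its own NH4+:N ratio; the projected ratio of the
    replenished solution is (NH4_end + ratio x added N) / target.  Shows how
    the starting ratio of a follow-on cultivation drifts below the stock's.
    """
    current = end_state.total_n_mm
    if target_total_n_mm < current:
        raise ValidationError(
            f"target total N {target_total_n_mm} mM below current {current} mM"
        )
    added_n = target_total_n_mm - current
    nh4_new = end_state.nh4 + stock_nh4_n_ratio * added_n
    return nh4_new / target_total_n_mm


def element_incorporation(shoot_dw_g: float, content_g_per_kg_dw: float) -> float:
    """Element mass (g) in biomass: dry weight x content / 1000."""
    if shoot_dw_g < 0 or content_g_per_kg_dw < 0:
        raise ValidationError("dry weight and content must be >= 0")
    return shoot_dw_g * content_g_per_kg_dw / 1000.0
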