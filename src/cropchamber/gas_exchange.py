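"""Chamber gas accounting: leak rates and daily crop O2 production.

A gas-tight cultivation chamber of fixed volume holds a mixture of O2, CO2
and inert gas (N2, Ar, ...).  Continuously logged O2 vol-%, CO2 ppmv,
pressure and temperature are converted to mole inventories through the ideal
gas law, n = P V / (R T).  Three physical facts drive the analysis:

* the crop exchanges only O2 and CO2, so the inert inventory decays purely
  through the chamber leak — its log-linear slope is a crop-independent leak
  estimator;
* daily net O2 production equals the day-over-day change in chamber O2 moles
  plus the O2 lost through the leak (and through any venting event);
* normalizing daily production by projected leaf area (PLA) yields a
  size-independent productivity, mol O2 d^-1 m^-2.

All internal arithmetic is unrounded; rounding happens only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Ambient atmosphere used when a vented chamber re-equilibrates with outside air.
AMBIENT_O2_PCT = 20.95
AMBIENT_CO2_PPMV = 420.0

SENSOR_COLUMNS = (
    "time_h",
    "dat",
    "is_day",
    "o2_pct",
    "co2_ppmv",
    "pressure_pa",
    "temp_k",
    "event",
)


def moles_total(pressure: float, temperature: float, volume: float) -> float:
    """Total gas moles in a volume from the ideal gas law, n = P V / (R T).

    Parameters are in Pa, K and m^3.  Pressure may be zero (vacuum);
    temperature and volume must be positive.
    """
    if temperature <= 0 or volume <= 0:
        raise ValidationError(
            f"temperature and volume must be positive (got T={temperature}, V={volume})"
        )
    if pressure < 0:
        raise ValidationError(f"pressure must be >= 0 (got {pressure})")
    return pressure * volume / (R_GAS * temperature)


def validate_sensor_series(series: pd.DataFrame) -> pd.DataFrame:
    """Check schema and physical ranges of a chamber sensor series.

    Returns the series sorted by time.  Raises :class:`ValidationError`
    naming the offending column or row.
    """
    missing = [c for c in SENSOR_COLUMNS if c not in series.columns]
    if missing:
        raise ValidationError(f"sensor series missing column(s): {', '.join(missing)}")
    out = series.sort_values("time_h").reset_index(drop=True)
    t = out["time_h"].to_numpy(float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise ValidationError(f"time_h not strictly increasing at row {i + 1}")
    if ((out["o2_pct"] < 0) | (out["o2_pct"] > 100)).any():
        raise ValidationError("o2_pct outside [0, 100]")
    if (out["co2_ppmv"] < 0).any():
        raise ValidationError("co2_ppmv negative")
    if (out["pressure_pa"] <= 0).any() or (out["temp_k"] <= 0).any():
        raise ValidationError("pressure_pa and temp_k must be positive")
    return out


def species_moles(series: pd.DataFrame, volume: float) -> pd.DataFrame:
    """Convert a sensor series to mole inventories per species.

    Adds columns ``n_total, n_o2, n_co2, n_inert`` (mol).  The inert channel
    is everything the crop neither produces nor consumes.
    """
    n_total = (
        series["pressure_pa"].to_numpy(float)
        * volume
        / (R_GAS * series["temp_k"].to_numpy(float))
    )
    n_o2 = n_total * series["o2_pct"].to_numpy(float) / 100.0
    n_co2 = n_total * series["co2_ppmv"].to_numpy(float) * 1e-6
    out = series.copy()
    out["n_total"] = n_total
    out["n_o2"] = n_o2
    out["n_co2"] = n_co2
    out["n_inert"] = n_total - n_o2 - n_co2
    return out


def estimate_leak_rate(series: pd.DataFrame, dat: int, volume: float) -> float:
    """Daily chamber leak rate (fractional loss per hour) from inert-gas decay.

    Fits ln(n_inert) against time over the 24 h window of day ``dat`` by
    ordinary least squares and converts the slope ``s`` to a per-step loss
    fraction, ``r = 1 - exp(s)``.  The inert inventory has no biological
    flux, so the fit is independent of crop activity.

    Raises if a venting event falls inside the window, if the window does
    not span the full day, or if the inert inventory is non-positive.
    """
    series = validate_sensor_series(series)
    t0, t1 = 24.0 * dat, 24.0 * (dat + 1)
    win = series[(series["time_h"] >= t0) & (series["time_h"] <= t1)]
    if len(win) < 3 or win["time_h"].iloc[0] > t0 or win["time_h"].iloc[-1] < t1:
        raise ValidationError(
            f"day {dat}: need samples spanning the full 24 h window [{t0}, {t1}] h"
        )
    if (win["event"] == "vent").any():
        raise ComputationError(f"day {dat}: venting event inside leak-estimation window")
    inv = species_moles(win, volume)
    n_inert = inv["n_inert"].to_numpy(float)
    if np.any(n_inert <= 0):
        raise ComputationError(f"day {dat}: non-positive inert inventory")
    t = inv["time_h"].to_numpy(float)
    slope = np.polyfit(t, np.log(n_inert), 1)[0]
    return float(1.0 - np.exp(slope))


def leak_rates_by_day(
    series: pd.DataFrame, volume: float
) -> tuple[dict[int, float], list[int]]:
    """Per-day leak rates for every complete day; vent days interpolated.

    Returns ``(rates, vent_days)`` where vent days carry the mean of their
    neighbouring days' estimates (or the single neighbour at the ends).
    """
    series = validate_sensor_series(series)
    t = series["time_h"].to_numpy(float)
    days = range(int(t[0] // 24), int(t[-1] // 24))
    rates: dict[int, float] = {}
    vent_days: list[int] = []
    for d in days:
        try:
            rates[d] = estimate_leak_rate(series, d, volume)
        except ComputationError:
            vent_days.append(d)
    for d in vent_days:
        neighbours = [rates[k] for k in (d - 1, d + 1) if k in rates]
        if not neighbours:
            raise ComputationError(f"day {d}: no vent-free neighbour for leak rate")
        rates[d] = float(np.mean(neighbours))
    return rates, vent_days


@dataclass
class DailyO2:
    """Per-day net O2 production and the leak rates used to correct it."""

    dat: np.ndarray          # day index
    o2_mol_per_d: np.ndarray  # net production, mol d^-1
    leak_per_h: np.ndarray    # fractional loss h^-1
    interpolated: np.ndarray  # True where a vent day was bridged

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dat": self.dat,
                "o2_mol_per_d": self.o2_mol_per_d,
                "leak_per_h": self.leak_per_h,
                "flag": np.where(self.interpolated, "interpolated", "ok"),
            }
        )


def daily_o2_production(
    series: pd.DataFrame,
    leaks: dict[int, float],
    volume: float,
    tank_adjustments: dict[int, float] | None = None,
    max_gap_h: float = 2.0,
) -> DailyO2:
    """Leak-corrected net O2 production per day (mol d^-1).

    For each complete day the production is the change in chamber O2 moles
    plus the integrated leak loss of O2 over that day.  The leak loss over a
    sampling interval ending at ``t_{i+1}`` is reconstructed as
    ``n_o2(t_{i+1}) * r*dt / (1 - r*dt)`` — exact when the chamber applies a
    per-interval survival factor ``(1 - r*dt)``, and accurate to O((r*dt)^2)
    in general.

    Vent days receive the supplied tank adjustment (mol O2 lost to venting)
    when available; otherwise their production is linearly interpolated from
    the neighbouring days and flagged.
    """
    series = validate_sensor_series(series)
    tank_adjustments = tank_adjustments or {}
    inv = species_moles(series, volume)
    t = inv["time_h"].to_numpy(float)
    gaps = np.diff(t)
    if np.any(gaps > max_gap_h):
        i = int(np.argmax(gaps > max_gap_h))
        raise ComputationError(
            f"sampling gap of {gaps[i]:.2f} h between {t[i]:.2f} and {t[i + 1]:.2f} h "
            f"exceeds {max_gap_h} h"
        )
    n_o2 = inv["n_o2"].to_numpy(float)
    events = inv["event"].to_numpy(object)
    day_first = int(t[0] // 24)
    day_last = int(t[-1] // 24)
    days = np.arange(day_first, day_last)
    prod = np.full(len(days), np.nan)
    interp = np.zeros(len(days), bool)
    for j, d in enumerate(days):
        if d not in leaks:
            raise ValidationError(f"no leak rate supplied for day {d}")
        r = leaks[d]
        sel = (t >= 24.0 * d) & (t <= 24.0 * (d + 1))
        idx = np.flatnonzero(sel)
        tt, nn = t[idx], n_o2[idx]
        vented = (events[idx] == "vent").any()
        if vented and d not in tank_adjustments:
            continue  # interpolated below
        dt_i = np.diff(tt)
        leak_loss = float(np.sum(nn[1:] * (r * dt_i) / (1.0 - r * dt_i)))
        prod[j] = (nn[-1] - nn[0]) + leak_loss + tank_adjustments.get(d, 0.0)
    missing = np.isnan(prod)
    if missing.any():
        if missing.all():
            raise ComputationError("no vent-free day available for production estimate")
        prod[missing] = np.interp(days[missing], days[~missing], prod[~missing])
        interp[missing] = True
    leak_arr = np.array([leaks[d] for d in days])
    return DailyO2(dat=days, o2_mol_per_d=prod, leak_per_h=leak_arr, interpolated=interp)


@dataclass
class PhaseSummary:
    """Totals and averages for a contiguous span of the crop test.

    Satisfies the identities ``avg_daily = total / duration`` and
    ``pla_specific = avg_daily / avg_pla`` exactly (before any rounding).
    """

    label: str
    duration_d: float
    total_o2_mol: float
    avg_pla_m2: float
    avg_daily_mol_per_d: float = field(init=False)
    pla_specific_mol_per_d_m2: float = field(init=False)

    def __post_init__(self):
        if self.duration_d <= 0:
            raise ValidationError("phase duration must be positive")
        self.avg_daily_mol_per_d = self.total_o2_mol / self.duration_d
        self.pla_specific_mol_per_d_m2 = (
            self.avg_daily_mol_per_d / self.avg_pla_m2 if self.avg_pla_m2 > 0 else np.nan
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "duration_d": self.duration_d,
            "total_o2_mol": self.total_o2_mol,
            "avg_pla_m2": self.avg_pla_m2,
            "avg_daily_mol_per_d": self.avg_daily_mol_per_d,
            "pla_specific_mol_per_d_m2": self.pla_specific_mol_per_d_m2,
        }


def phase_summary(
    daily: DailyO2,
    pla,
    phase: tuple[float, float],
    label: str | None = None,
    exclude_interpolated: bool = True,
) -> PhaseSummary:
    """Summarise daily production over ``phase = (start DAT, end DAT)``.

    ``pla`` is a :class:`~cropchamber.canopy_growth.PLAISeries`.  Total O2 is
    the sum of daily values for days in ``[start, end)``; vent days bridged by
    interpolation are excluded from the total and the duration (matching the
    convention of reporting the full period "not accounting for the day of
    venting").  Average PLA is the trapezoidal time-mean of linearly
    interpolated PLA over the phase.
    """
    from .canopy_growth import interpolate_pla

    start, end = phase
    if end <= start:
        raise ValidationError(f"zero-length phase {phase}")
    sel = (daily.dat >= start) & (daily.dat < end)
    if not sel.any():
        raise ValidationError(f"phase {phase} outside the data range")
    use = sel & (~daily.interpolated if exclude_interpolated else np.ones_like(sel))
    total = float(np.sum(daily.o2_mol_per_d[use]))
    duration = float(np.sum(use))
    tgrid = np.linspace(start, end, 201)
    pla_vals = np.array([interpolate_pla(pla, tt) for tt in tgrid])
    avg_pla = float(np.trapezoid(pla_vals, tgrid) / (end - start))
    return PhaseSummary(
        label=label or f"{start:g}-{end:g} DAT",
        duration_d=duration,
        total_o2_mol=total,
        avg_pla_m2=avg_pla,
    )


def smooth_polynomial(
    dat: np.ndarray, values: np.ndarray, degree: int = 3
) -> np.ndarray:
    """Least-squares polynomial smoothing evaluated at the input days."""
    dat = np.asarray(dat, float)
    values = np.asarray(values, float)
    if len(dat) < degree + 1:
        raise ValidationError(
            f"need at least {degree + 1} points for degree-{degree} smoothing, got {len(dat)}"
        )
    poly = np.polynomial.Polynomial.fit(dat, values, degree)
    return poly(dat)


def pla_specific_series(dat: np.ndarray, daily_o2: np.ndarray, pla) -> np.ndarray:
    """Daily O2 production per projected leaf area, mol d^-1 m^-2.

    PLA is linearly interpolated between its (typically 2-day) samples;
    a zero PLA at an evaluated day is an error.
    """
    from .canopy_growth import interpolate_pla

    dat = np.asarray(dat, float)
    daily_o2 = np.asarray(daily_o2, float)
    pla_vals = np.array([interpolate_pla(pla, d) for d in dat])
    if np.any(pla_vals <= 0):
        bad = dat[pla_vals <= 0][0]
        raise ComputationError(f"PLA is zero at DAT {bad:g}; cannot normalise")
    return daily_o2 / pla_vals
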