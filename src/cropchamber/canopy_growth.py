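"""Canopy growth metrics from projected leaf area.

Inside a sealed chamber the crop cannot be weighed, so growth is tracked
non-destructively from top-view images.  The Projected Leaf Area Index
(PLAI) is the canopy silhouette area of all plants divided by the
cultivation floor area; it is dimensionless and bounded by 1.  During the
close-to-exponential phase the specific growth rate

    mu_PLAI = (d PLAI / dt) / PLAI        [d^-1]

is approximately constant, and an exponential regression of PLAI over that
window estimates it directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass
class PLAISeries:
    """PLAI samples over time plus the floor area they refer to."""

    dat: np.ndarray            # days after transplant, strictly increasing
    plai: np.ndarray           # m^2 m^-2, in [0, 1]
    cultivation_area: float = 1.8  # m^2

    def __post_init__(self):
        self.dat = np.asarray(self.dat, float)
        self.plai = np.asarray(self.plai, float)
        if self.dat.shape != self.plai.shape or self.dat.ndim != 1:
            raise ValidationError("dat and plai must be 1-d arrays of equal length")
        if len(self.dat) and np.any(np.diff(self.dat) <= 0):
            raise ValidationError("dat must be strictly increasing")
        if np.any(self.plai < 0) or np.any(self.plai > 1):
            raise ValidationError("plai must lie in [0, 1]")
        if self.cultivation_area <= 0:
            raise ValidationError("cultivation_area must be positive")

    @property
    def pla(self) -> np.ndarray:
        """Projected leaf area in m^2."""
        return self.plai * self.cultivation_area


@dataclass
class GrowthFit:
    """Exponential-regression result: PLAI(t) ~ a0 * exp(mu * t)."""

    mu: float        # specific growth rate, d^-1
    a0: float        # fitted PLAI at t = 0
    r2: float        # coefficient of determination on the log scale
    window: tuple[float, float]


def compute_plai(projected_area: float, cultivation_area: float) -> float:
    """PLAI = projected leaf area / cultivation floor area.

    The projection of a canopy cannot exceed the floor it stands on
    (overlapping leaves make the projection sub-additive), so
    ``projected_area > cultivation_area`` is rejected.
    """
    if cultivation_area <= 0:
        raise ValidationError("cultivation_area must be positive")
    if projected_area < 0 or projected_area > cultivation_area:
        raise ValidationError(
            f"projected area {projected_area} m^2 outside [0, {cultivation_area}] m^2"
        )
    return projected_area / cultivation_area


def mu_plai_series(series: PLAISeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample specific growth rate mu_PLAI (d^-1).

    Interior samples use the central log-difference
    ``(ln p[i+1] - ln p[i-1]) / (t[i+1] - t[i-1])`` — exact for exponential
    growth, the regime the metric describes.  The two endpoints fall back to
    one-sided differences and are flagged lower-confidence.

    Returns ``(mu, endpoint_flag)``.
    """
    t, p = series.dat, series.plai
    if len(t) < 3:
        raise ValidationError("need at least 3 samples for mu_PLAI")
    if np.any(p <= 0):
        raise ValidationError("all plai values must be positive for mu_PLAI")
    lp = np.log(p)
    mu = np.empty_like(lp)
    mu[1:-1] = (lp[2:] - lp[:-2]) / (t[2:] - t[:-2])
    mu[0] = (lp[1] - lp[0]) / (t[1] - t[0])
    mu[-1] = (lp[-1] - lp[-2]) / (t[-1] - t[-2])
    flag = np.zeros(len(t), bool)
    flag[[0, -1]] = True
    return mu, flag


def smooth_plai(series: PLAISeries, window: int = 3) -> PLAISeries:
    """Optional centred moving-average pre-smoother (off by default upstream)."""
    from .nutrient_balance import moving_average

    return PLAISeries(
        dat=series.dat,
        plai=moving_average(series.plai, window),
        cultivation_area=series.cultivation_area,
    )


def fit_exponential(series: PLAISeries, window: tuple[float, float]) -> GrowthFit:
    """Log-linear OLS fit of PLAI within ``window = (start, end)`` DAT.

    Ordinary least squares of ln(PLAI) on time gives ``mu`` as the slope and
    ``a0 = exp(intercept)``; R^2 is computed on the log scale.  This matches
    the spreadsheet "exponential trendline" convention.
    """
    start, end = window
    sel = (series.dat >= start) & (series.dat <= end)
    t, p = series.dat[sel], series.plai[sel]
    if len(t) < 2 or np.ptp(t) == 0:
        raise ValidationError(f"window {window} leaves <2 distinct samples")
    if np.any(p <= 0):
        raise ValidationError("all plai values in the window must be positive")
    res = stats.linregress(t, np.log(p))
    return GrowthFit(
        mu=float(res.slope),
        a0=float(np.exp(res.intercept)),
        r2=float(res.rvalue**2),
        window=(float(start), float(end)),
    )


def interpolate_pla(series: PLAISeries, t: float) -> float:
    """Projected leaf area (m^2) at time ``t``, linearly interpolated.

    Outside the sampled range the series is clamped to its end values.
    """
    if len(series.dat) == 0:
        raise ValidationError("empty PLAI series")
    plai_t = float(np.interp(t, series.dat, series.plai))
    return plai_t * series.cultivation_area
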