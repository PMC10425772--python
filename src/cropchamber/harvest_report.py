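"""Per-plant harvest metrics and two-group crop comparisons.

Each crop test ends with destructive sampling of all plants: fresh and dry
weights of shoot and root, leaf counts and areas.  Derived per-plant metrics
follow the usual horticultural definitions — dry-weight content (% of fresh
weight), harvest index (shoot DW over total DW) and root:shoot ratio (on dry
weight).  Group summaries are per-plant-then-mean; two-group contrasts
report the percent difference together with both a Welch t-test and a
Mann-Whitney rank test, the headline p chosen by a normality screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .nutrient_balance import element_incorporation

METRIC_FIELDS = (
    "shoot_fw_g",
    "shoot_dw_g",
    "root_dw_g",
    "leaf_count",
    "leaf_area_cm2",
    "stem_diameter_mm",
)


@dataclass
class PlantHarvestRecord:
    plant_id: str
    shoot_fw_g: float
    shoot_dw_g: float
    root_dw_g: float
    leaf_count: int = 0
    leaf_area_cm2: float = 0.0
    stem_diameter_mm: float = float("nan")
    covariates: dict | None = None  # e.g. SPAD, Fv/Fm, colour L/a/b

    def __post_init__(self):
        if min(self.shoot_fw_g, self.shoot_dw_g, self.root_dw_g) < 0:
            raise ValidationError(f"plant {self.plant_id}: negative weight")
        if self.shoot_dw_g > self.shoot_fw_g:
            raise ValidationError(
                f"plant {self.plant_id}: shoot DW exceeds shoot FW"
            )


def plant_metrics(record: PlantHarvestRecord) -> dict:
    """Dry-weight content (%), harvest index, and root:shoot ratio."""
    if record.shoot_fw_g <= 0:
        raise ValidationError(f"plant {record.plant_id}: shoot FW must be positive")
    total_dw = record.shoot_dw_g + record.root_dw_g
    if total_dw <= 0:
        raise ValidationError(f"plant {record.plant_id}: total DW must be positive")
    return {
        "dw_content_pct": 100.0 * record.shoot_dw_g / record.shoot_fw_g,
        "harvest_index": record.shoot_dw_g / total_dw,
        "root_shoot": record.root_dw_g / record.shoot_dw_g
        if record.shoot_dw_g > 0
        else float("inf"),
    }


def group_summary(records: list[PlantHarvestRecord]) -> pd.DataFrame:
    """Mean +/- sample SD per metric, plants as replicates.

    Ratio metrics are averaged per-plant-then-mean (a mean of ratios, not a
    ratio of means); the pooled-ratio alternative is surfaced separately by
    :func:`crop_totals` so the difference is visible, not hidden.
    """
    if len(records) < 1:
        raise ValidationError("no harvest records")
    rows = []
    for r in records:
        row = {f: getattr(r, f) for f in METRIC_FIELDS}
        row.update(plant_metrics(r))
        rows.append(row)
    df = pd.DataFrame(rows)
    out = pd.DataFrame({"mean": df.mean()})
    out["sd"] = df.std(ddof=1) if len(records) >= 2 else np.nan
    out["n"] = len(records)
    out["sd_defined"] = len(records) >= 2
    return out


def group_compare(a, b) -> dict:
    """Two-group contrast: percent difference plus parametric and rank tests.

    ``pct_difference = 100 (mean_a - mean_b) / mean_a`` (positive when group
    b is lower).  A Welch t-test and a Mann-Whitney U test are both always
    reported; a Shapiro-Wilk screen on each group (alpha = 0.05) selects the
    headline p — rank-based if either group departs from normality.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    mean_a, mean_b = a.mean(), b.mean()
    if mean_a == 0:
        raise ValidationError("group a mean is zero; percent difference undefined")
    pct = 100.0 * (mean_a - mean_b) / mean_a
    if np.ptp(a) == 0 and np.ptp(b) == 0 and mean_a == mean_b:
        # identical constant groups: both tests are degenerate, p := 1
        p_t = 1.0
        u_p = 1.0
        normal = True
    else:
        t_res = stats.ttest_ind(a, b, equal_var=False)
        p_t = float(t_res.pvalue) if np.isfinite(t_res.pvalue) else 1.0
        u_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        normal = (
            np.ptp(a) > 0
            and np.ptp(b) > 0
            and stats.shapiro(a).pvalue >= 0.05
            and stats.shapiro(b).pvalue >= 0.05
        )
    return {
        "pct_difference": pct,
        "p_normal": p_t,
        "p_rank": u_p,
        "p_headline": p_t if normal else u_p,
        "normality_ok": bool(normal),
    }


def crop_totals(
    records: list[PlantHarvestRecord],
    element_contents: dict[tuple[str, str], float] | None = None,
) -> dict:
    """Whole-crop sums per compartment plus element masses.

    ``element_contents`` maps ``(compartment, element) -> g per kg DW``,
    e.g. ``("shoot", "C"): 382``.  Element masses use the compartment DW sum
    via :func:`~cropchamber.nutrient_balance.element_incorporation`.
    """
    if not records:
        raise ValidationError("no harvest records")
    shoot_dw = float(sum(r.shoot_dw_g for r in records))
    root_dw = float(sum(r.root_dw_g for r in records))
    out = {
        "n_plants": len(records),
        "shoot_fw_g": float(sum(r.shoot_fw_g for r in records)),
        "shoot_dw_g": shoot_dw,
        "root_dw_g": root_dw,
        "leaf_area_cm2": float(sum(r.leaf_area_cm2 for r in records)),
        # pooled-ratio counterparts of the per-plant-then-mean summaries
        "pooled_harvest_index": shoot_dw / (shoot_dw + root_dw)
        if shoot_dw + root_dw > 0
        else float("nan"),
        "pooled_root_shoot": root_dw / shoot_dw if shoot_dw > 0 else float("nan"),
        "elements_g": {},
    }
    if element_contents:
        dw = {"shoot": shoot_dw, "root": root_dw}
        for (compartment, element), content in element_contents.items():
            if compartment not in dw:
                raise ValidationError(
                    f"unknown compartment {compartment!r} for element {element}"
                )
            out["elements_g"][(compartment, element)] = element_incorporation(
                dw[compartment], content
            )
    return out
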