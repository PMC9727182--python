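"""Concentration-effect analysis of the cardiomyocyte protection assay.

Protection rate of a pretreatment against H2O2 injury is the MTT OD570
recovery relative to the normal/model span:

    rate = (OD_treated - OD_model) / (OD_normal - OD_model) x 100%.

Rates measured at several molar concentrations form an
:class:`EffectCurve`; its trapezoidal area over a concentration range is
``AUC_effect`` (%·µM), the quantity behind the effect-weighting
coefficients of the integrated PK.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PKValidationError

__all__ = [
    "EffectCurve",
    "EffectAUC",
    "DegenerateAssayError",
    "protection_rate",
    "protection_rate_table",
    "build_effect_curve",
    "effect_auc",
    "effect_validated",
]


class DegenerateAssayError(ValueError):
    """The normal and model groups are indistinguishable (zero assay span)."""


@dataclass(frozen=True)
class EffectCurve:
    """Protection rate (%) vs molar concentration (µM) for one analyte.

    Concentrations strictly increase; rates may be negative or exceed 100
    (they are ratios of OD differences, not probabilities).
    """

    analyte: str
    concentrations: np.ndarray  # µM
    rates: np.ndarray  # percent

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations",
                           np.asarray(self.concentrations, dtype=float))
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if self.concentrations.shape != self.rates.shape:
            raise PKValidationError("concentrations and rates must match in length")
        if np.any(np.diff(self.concentrations) <= 0):
            raise PKValidationError("concentrations must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise PKValidationError("concentrations must be >= 0")


@dataclass(frozen=True)
class EffectAUC:
    """Area under one analyte's protection-rate curve over a µM range."""

    analyte: str
    auc_effect: float  # %·µM
    c_lo: float
    c_hi: float
    normalized: bool = False  # True when divided by the range width


def protection_rate(od_admin, od_model, od_normal) -> float:
    """Protection rate (%) of a treated group.

    Replicate vectors are averaged first; the result is
    ``(mean_admin - mean_model)/(mean_normal - mean_model) * 100``.
    """
    a = float(np.mean(od_admin))
    m = float(np.mean(od_model))
    n = float(np.mean(od_normal))
    if n == m:
        raise DegenerateAssayError("OD_normal equals OD_model: assay span is zero")
    return (a - m) / (n - m) * 100.0


def protection_rate_table(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-treated-group protection rates from an OD plate table.

    Expects columns ``group, conc_uM, replicate, od570`` with reserved group
    labels ``normal`` and ``model``; every other group gets a rate.
    """
    for col in ("group", "od570"):
        if col not in plate.columns:
            raise PKValidationError(f"plate table lacks column {col!r}")
    means = plate.groupby("group")["od570"].mean()
    if "normal" not in means or "model" not in means:
        raise PKValidationError("plate table needs 'normal' and 'model' groups")
    rows = []
    for group, sub in plate.groupby("group"):
        if group in ("normal", "model"):
            continue
        rate = protection_rate(sub["od570"].to_numpy(),
                               means["model"], means["normal"])
        conc = sub["conc_uM"].iloc[0] if "conc_uM" in sub else np.nan
        rows.append((group, float(conc), rate))
    return pd.DataFrame(rows, columns=["group", "conc_uM", "protection_rate_pct"])


def build_effect_curve(
    analyte: str,
    points: Sequence[tuple[float, float]],
    anchor_zero: bool = True,
) -> EffectCurve:
    """Assemble a protection-rate curve from (µM, %) points.

    Points are sorted by concentration; with ``anchor_zero`` (default) the
    point (0 µM, 0%) is prepended — no drug means model-group OD, hence 0%
    by the protection-rate formula.
    """
    if len(points) == 0:
        raise PKValidationError("need at least one (concentration, rate) point")
    pts = sorted((float(c), float(r)) for c, r in points)
    concs = [c for c, _ in pts]
    if len(set(concs)) != len(concs):
        raise PKValidationError("duplicate concentrations in effect curve")
    if anchor_zero and (not concs or concs[0] > 0):
        pts = [(0.0, 0.0)] + pts
    return EffectCurve(
        analyte=analyte,
        concentrations=np.array([c for c, _ in pts]),
        rates=np.array([r for _, r in pts]),
    )


def effect_auc(
    curve: EffectCurve,
    c_range: tuple[float, float],
    normalized: bool = False,
    clip_negative: bool = False,
) -> EffectAUC:
    """Trapezoidal AUC_effect (%·µM) of a curve over ``[c_lo, c_hi]``.

    Linear interpolation between measured points; the range must lie within
    the (anchored) curve span — no silent flat extrapolation.  With
    ``normalized`` the area is divided by the range width (units become %),
    a convention that changes weights only when analytes use unequal ranges.
    Negative rates are retained unless ``clip_negative``.
    """
    lo, hi = float(c_range[0]), float(c_range[1])
    c, r = curve.concentrations, curve.rates
    if lo < c[0] or hi > c[-1]:
        raise PKValidationError(
            f"range [{lo}, {hi}] outside curve span [{c[0]}, {c[-1]}]"
        )
    if hi < lo:
        raise PKValidationError("empty range")
    inner = c[(c > lo) & (c < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, c, r)
    if clip_negative:
        vals = np.clip(vals, 0.0, None)
    area = float(np.trapezoid(vals, grid))
    if normalized:
        if hi == lo:
            raise PKValidationError("cannot normalize a zero-width range")
        area /= hi - lo
    return EffectAUC(curve.analyte, area, lo, hi, normalized=normalized)


def effect_validated(plate: pd.DataFrame, alpha: float = 0.05) -> bool:
    """Whether any tested concentration protects significantly.

    One-sided two-sample t-test of treated vs model replicate ODs
    (treated > model) at each concentration; True if any p < alpha.
    """
    model = plate.loc[plate["group"] == "model", "od570"].to_numpy()
    if model.size < 2:
        raise PKValidationError("need >= 2 model replicates")
    for group, sub in plate.groupby("group"):
        if group in ("normal", "model", "positive"):
            continue
        treated = sub["od570"].to_numpy()
        if treated.size < 2:
            continue
        p = stats.ttest_ind(treated, model, alternative="greater").pvalue
        if p < alpha:
            return True
    return False
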