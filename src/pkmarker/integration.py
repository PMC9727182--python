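"""Integrated ("virtual single-analyte") pharmacokinetics.

Several co-dosed analytes are collapsed into one concentration-time course
per subject by one of three constructions:

* ``sum`` — plasma drug concentration sum, C_Z(t) = sum_i C_i(t);
* ``auc`` — AUC-weighted, omega_i = AUC_i / sum_j AUC_j;
* ``effect`` — effect-weighted, omega_i = AUC_i^effect / sum_j AUC_j^effect,

followed by C_Z(t) = sum_i omega_i C_i(t) and ordinary NCA of the virtual
profile.  The virtual analyte's dose is the matching combination
sum_i omega_i dose_i, so clearance and volume stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PKProfile, PKValidationError
from .nca import compute_nca, nca_group_summary, nca_table

__all__ = [
    "IntegrationWeights",
    "concentration_sum",
    "auc_weights",
    "effect_weights",
    "weighted_integration",
    "integrate_cohort",
    "integrated_nca_summary",
]

_METHODS = ("sum", "auc", "effect")


@dataclass(frozen=True)
class IntegrationWeights:
    """Per-analyte weights omega_i for a named integration method.

    For the ``auc`` and ``effect`` methods the weights lie in [0, 1] and sum
    to 1; the ``sum`` method uses the convention omega_i = 1 for all i.
    """

    method: str
    omegas: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise PKValidationError(f"method must be one of {_METHODS}")
        object.__setattr__(self, "omegas", dict(self.omegas))
        vals = np.array(list(self.omegas.values()), dtype=float)
        if self.method == "sum":
            if not np.all(vals == 1.0):
                raise PKValidationError("'sum' weights are 1 by convention")
        else:
            if np.any(vals < 0) or np.any(vals > 1):
                raise PKValidationError("weights must lie in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-12:
                raise PKValidationError(f"weights must sum to 1, got {vals.sum()!r}")


def _normalize(values: Mapping[str, float], method: str) -> IntegrationWeights:
    vals = {k: float(v) for k, v in values.items()}
    if any(v < 0 for v in vals.values()):
        raise PKValidationError("weight inputs must be >= 0")
    total = sum(vals.values())
    if total <= 0:
        raise PKValidationError("at least one input must be > 0")
    return IntegrationWeights(method, {k: v / total for k, v in vals.items()})


def auc_weights(aucs: Mapping[str, float]) -> IntegrationWeights:
    """AUC-share weights: omega_i = AUC_i / sum_j AUC_j."""
    return _normalize(aucs, "auc")


def effect_weights(effect_aucs: Mapping[str, float]) -> IntegrationWeights:
    """Effect-weighting coefficients from per-analyte AUC_effect (%·µM)."""
    return _normalize(effect_aucs, "effect")


def _common_grid(profiles: Sequence[PKProfile]) -> np.ndarray:
    grid = profiles[0].times
    for p in profiles[1:]:
        if p.times.shape != grid.shape or not np.allclose(p.times, grid):
            raise PKValidationError(
                "profiles must share one sampling grid (no resampling is done)"
            )
        if p.subject_id != profiles[0].subject_id:
            raise PKValidationError("profiles must belong to one subject")
    return grid


def _combine(profiles: Sequence[PKProfile], weights: IntegrationWeights) -> PKProfile:
    grid = _common_grid(profiles)
    missing = [p.analyte for p in profiles if p.analyte not in weights.omegas]
    if missing:
        raise PKValidationError(f"no weight for analyte(s): {missing}")
    cz = np.zeros_like(grid)
    for p in profiles:
        contrib = np.where(p.blq, 0.0, p.concentrations)  # BLQ contributes 0
        cz = cz + weights.omegas[p.analyte] * contrib
    return PKProfile(
        subject_id=profiles[0].subject_id,
        dose_group=profiles[0].dose_group,
        volume_dose=profiles[0].volume_dose,
        analyte=f"integrated-{weights.method}",
        times=grid,
        concentrations=cz,
        blq=np.zeros(grid.shape, dtype=bool),
    )


def concentration_sum(profiles: Sequence[PKProfile]) -> PKProfile:
    """Plasma-concentration-sum profile of one subject: C_Z = sum_i C_i."""
    if not profiles:
        raise PKValidationError("need at least one profile")
    w = IntegrationWeights("sum", {p.analyte: 1.0 for p in profiles})
    return _combine(profiles, w)


def weighted_integration(
    profiles: Sequence[PKProfile], weights: IntegrationWeights
) -> PKProfile:
    """Weighted integrated profile of one subject: C_Z = sum_i omega_i C_i."""
    if not profiles:
        raise PKValidationError("need at least one profile")
    return _combine(profiles, weights)


def _by_subject(profiles: Iterable[PKProfile]) -> dict[str, list[PKProfile]]:
    out: dict[str, list[PKProfile]] = {}
    for p in profiles:
        out.setdefault(p.subject_id, []).append(p)
    return out


def integrate_cohort(
    profiles: Iterable[PKProfile],
    weights: IntegrationWeights,
) -> list[PKProfile]:
    """Apply one integration to every subject of a cohort."""
    out = []
    for subject, plist in _by_subject(profiles).items():
        if weights.method == "sum":
            w = IntegrationWeights("sum", {p.analyte: 1.0 for p in plist})
            out.append(_combine(plist, w))
        else:
            out.append(_combine(plist, weights))
    return out


def integrated_dose(weights: IntegrationWeights, doses: Mapping[str, float]) -> float:
    """Dose (µg/kg) of the virtual analyte: sum_i omega_i dose_i."""
    missing = [a for a in weights.omegas if a not in doses]
    if missing:
        raise PKValidationError(f"no dose for analyte(s): {missing}")
    return float(sum(weights.omegas[a] * doses[a] for a in weights.omegas))


def integrated_nca_summary(
    profiles: Iterable[PKProfile],
    weights: IntegrationWeights,
    doses: Mapping[str, float],
    rule: str = "linear",
    return_subject_table: bool = False,
):
    """Integrate per subject, run NCA per subject, summarize mean +/- SD.

    ``doses`` maps analyte -> content of the preparation (µg/ml); each
    subject's mass dose is content x its volume dose (ml/kg), and the
    virtual analyte's dose is the omega-weighted combination of those.
    Inestimable terminal phases propagate as NaN cells in the summary.
    """
    results = []
    for subject, plist in _by_subject(profiles).items():
        if weights.method == "sum":
            w = IntegrationWeights("sum", {p.analyte: 1.0 for p in plist})
        else:
            w = weights
        integ = _combine(plist, w)
        per_analyte_dose = {
            p.analyte: doses[p.analyte] * p.volume_dose for p in plist
        }
        d = integrated_dose(w, per_analyte_dose)
        results.append(compute_nca(integ, d, rule=rule))
    if return_subject_table:
        return nca_group_summary(results), nca_table(results)
    return nca_group_summary(results)
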