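"""Multi-criteria PK-marker screening.

A single ingredient qualifies as the PK marker of a multi-ingredient
preparation when it simultaneously

1. shows favorable PK (terminal phase estimable at an ordinary dose),
2. statistically represents the integrated multi-ingredient kinetics
   (no PK parameter differs significantly from the integrated profile),
3. is annotated as relevant to the target disease, and
4. has an experimentally validated pharmacological effect.

The intersection of the four criterion sets is the marker set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PKValidationError
from .nca import NCA_PARAMETERS

__all__ = [
    "CriterionFlags",
    "RepresentativenessReport",
    "MarkerScreenReport",
    "estimability_from_nca",
    "favorable_pk",
    "representativeness_test",
    "screen_markers",
]

CRITERIA = ("favorable_pk", "representative", "cvd_relevant", "effect_validated")


@dataclass(frozen=True)
class CriterionFlags:
    """Screening flags for one analyte.

    ``representative`` is only meaningful for analytes with favorable PK;
    it is forced False otherwise (an analyte whose parameters cannot even be
    estimated at ordinary doses cannot represent the preparation).
    """

    analyte: str
    favorable_pk: bool
    representative: bool
    cvd_relevant: bool
    effect_validated: bool

    def __post_init__(self) -> None:
        if self.representative and not self.favorable_pk:
            object.__setattr__(self, "representative", False)

    def all_true(self) -> bool:
        return (
            self.favorable_pk
            and self.representative
            and self.cvd_relevant
            and self.effect_validated
        )


@dataclass
class RepresentativenessReport:
    """Per-parameter x per-dose comparison of a candidate vs integrated PK."""

    analyte: str
    table: pd.DataFrame  # columns: parameter, dose_group, p_value, significant, evaluable
    alpha: float

    @property
    def representative(self) -> bool:
        """True when no evaluable parameter differs significantly."""
        ev = self.table[self.table["evaluable"]]
        return not bool(ev["significant"].any())


@dataclass
class MarkerScreenReport:
    """Outcome of the four-criteria screen across all analytes."""

    flags: list[CriterionFlags]
    markers: set[str] = field(init=False)
    criterion_sets: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.criterion_sets = {
            c: {f.analyte for f in self.flags if getattr(f, c)} for c in CRITERIA
        }
        self.markers = set.intersection(*self.criterion_sets.values())

    def venn_regions(self) -> dict[frozenset, set[str]]:
        """Exact membership regions: which analytes satisfy exactly which
        subset of criteria (for a textual Venn rendering)."""
        regions: dict[frozenset, set[str]] = {}
        for f in self.flags:
            key = frozenset(c for c in CRITERIA if getattr(f, c))
            regions.setdefault(key, set()).add(f.analyte)
        return regions


def estimability_from_nca(
    nca_table: pd.DataFrame, min_estimable: int = 2
) -> pd.DataFrame:
    """Analyte x dose-group table of terminal-phase estimability.

    A group counts as estimable when at least ``min_estimable`` subjects have
    a finite half-life (so a mean +/- SD could be reported for the cell).
    """
    ok = nca_table.assign(est=np.isfinite(nca_table["t_half"]))
    counts = ok.groupby(["analyte", "dose_group"])["est"].sum().unstack()
    return counts >= min_estimable


def favorable_pk(
    estimable: pd.DataFrame | Mapping[str, str],
    dose_order: Sequence[str] = ("low", "medium", "high"),
    reference_dose: str = "medium",
) -> set[str]:
    """Analytes with favorable PK: terminal phase estimable at a dose no
    higher than ``reference_dose``.

    ``estimable`` is either a boolean analyte x dose-group frame (from
    :func:`estimability_from_nca`) or a mapping analyte -> lowest estimable
    dose group.  Analytes estimable only above the reference dose (e.g. only
    at the highest dose) are excluded.
    """
    if reference_dose not in dose_order:
        raise PKValidationError(f"{reference_dose!r} not in dose order {dose_order}")
    cutoff = list(dose_order).index(reference_dose)
    if isinstance(estimable, pd.DataFrame):
        if estimable.empty:
            raise PKValidationError("empty estimability table")
        out = set()
        for analyte, row in estimable.iterrows():
            for d in dose_order[: cutoff + 1]:
                if d in row.index and bool(row[d]):
                    out.add(analyte)
                    break
        return out
    if not estimable:
        raise PKValidationError("empty detection pattern")
    return {
        a
        for a, lowest in estimable.items()
        if lowest in dose_order and list(dose_order).index(lowest) <= cutoff
    }


def representativeness_test(
    candidate: pd.DataFrame,
    integrated: pd.DataFrame,
    alpha: float = 0.05,
    tail: str = "single",
    parameters: Sequence[str] = tuple(NCA_PARAMETERS),
) -> RepresentativenessReport:
    """Compare a candidate analyte's per-subject NCA with the integrated PK.

    Both inputs are tidy per-subject tables (as from ``nca_table``) with a
    ``dose_group`` column.  For every parameter and dose group with at least
    two finite values on each side, an unpaired two-sample t-test is run;
    with ``tail='single'`` the p-value is one-sided in the direction of the
    observed mean difference (half the two-sided p), following the original
    analysis — a data-directed single tail is anti-conservative, and
    ``tail='two'`` is available.  The analyte is representative when no
    evaluable cell is significant.
    """
    if tail not in ("single", "two"):
        raise PKValidationError("tail must be 'single' or 'two'")
    rows = []
    doses = sorted(set(candidate["dose_group"]) & set(integrated["dose_group"]))
    if not doses:
        raise PKValidationError("no shared dose groups")
    for param in parameters:
        for dose in doses:
            x = candidate.loc[candidate["dose_group"] == dose, param].to_numpy(float)
            y = integrated.loc[integrated["dose_group"] == dose, param].to_numpy(float)
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            if len(x) < 2 or len(y) < 2:
                rows.append((param, dose, np.nan, False, False))
                continue
            res = stats.ttest_ind(x, y)
            p = float(res.pvalue)
            if tail == "single":
                p = p / 2.0
            if np.isnan(p):  # zero variance on both sides, equal means
                p = 1.0
            rows.append((param, dose, p, p < alpha, True))
    table = pd.DataFrame(
        rows, columns=["parameter", "dose_group", "p_value", "significant", "evaluable"]
    )
    analyte = candidate["analyte"].iloc[0] if "analyte" in candidate else "candidate"
    return RepresentativenessReport(analyte=str(analyte), table=table, alpha=alpha)


def screen_markers(flags: Iterable[CriterionFlags]) -> MarkerScreenReport:
    """Intersect the four criterion sets into the final marker call.

    An empty marker set is a valid outcome; the report also exposes every
    exact criterion-combination region for Venn-style presentation.
    """
    flags = list(flags)
    if not flags:
        raise PKValidationError("no analytes to screen")
    names = [f.analyte for f in flags]
    if len(set(names)) != len(names):
        raise PKValidationError("duplicate analyte flags")
    return MarkerScreenReport(flags)
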