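"""Tabular input/output, domain containers and unit conversions.

Plasma concentrations are carried in ng/ml, preparation contents in µg/ml,
times in hours and doses in ml/kg (volume of injection) or µg/kg (mass of a
single analyte).  All unit changes are explicit operations; nothing converts
implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteInfo",
    "PKProfile",
    "ContentTable",
    "ANALYTE_REGISTRY",
    "PKTableFormatError",
    "PKValidationError",
    "read_pk_table",
    "write_pk_table",
    "read_content_table",
    "mass_to_molar",
    "analyte_dose",
]

PK_TABLE_COLUMNS = (
    "subject_id",
    "dose_group",
    "dose_ml_per_kg",
    "analyte",
    "time_h",
    "conc_ng_per_ml",
    "blq",
)


class PKTableFormatError(ValueError):
    """A delimited input file does not have the expected layout."""


class PKValidationError(ValueError):
    """Input values violate a domain invariant (ordering, sign, shape)."""


@dataclass(frozen=True)
class AnalyteInfo:
    """Identity and physico-chemical metadata for one analyte.

    Parameters
    ----------
    name
        Analyte identifier, unique within a registry.
    molecular_weight
        Molar mass in g/mol; must be finite and positive.
    lod
        Limit of detection of the bioassay in ng/ml (>= 0).
    """

    name: str
    molecular_weight: float
    lod: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.molecular_weight) or self.molecular_weight <= 0:
            raise PKValidationError(
                f"molecular_weight must be finite and > 0, got {self.molecular_weight}"
            )
        if self.lod < 0:
            raise PKValidationError(f"lod must be >= 0, got {self.lod}")


#: Molar masses (g/mol) of the six plasma-quantified ingredients of the
#: safflower-injection preparation, consistent with the printed µg/ml <-> µM
#: concentration pairs for HSYA and SYR.
ANALYTE_REGISTRY: Mapping[str, AnalyteInfo] = {
    a.name: a
    for a in (
        AnalyteInfo("HSYA", 612.53),
        AnalyteInfo("SYR", 372.37),
        AnalyteInfo("p-CA", 164.16),
        AnalyteInfo("SCU", 462.36),
        AnalyteInfo("p-HBA", 122.12),
        AnalyteInfo("RU", 610.52),
    )
}


@dataclass
class PKProfile:
    """One subject x analyte concentration-time course after an IV bolus.

    Concentrations below the limit of quantification are stored as 0 with the
    matching ``blq`` flag set, which keeps arrays rectangular while preserving
    the censoring information.
    """

    subject_id: str
    dose_group: str
    volume_dose: float  # ml/kg
    analyte: str
    times: np.ndarray  # hours
    concentrations: np.ndarray  # ng/ml
    blq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.blq is None:
            self.blq = np.zeros(self.times.shape, dtype=bool)
        self.blq = np.asarray(self.blq, dtype=bool)
        if self.times.size == 0:
            raise PKValidationError("a profile needs at least one record")
        if self.times.shape != self.concentrations.shape or self.times.shape != self.blq.shape:
            raise PKValidationError("times, concentrations and blq must share a shape")
        if np.any(np.diff(self.times) <= 0):
            raise PKValidationError(
                f"times must be strictly increasing for {self.subject_id}/{self.analyte}"
            )
        if np.any(self.times < 0):
            raise PKValidationError("times must be >= 0")
        if np.any(self.concentrations[~self.blq] < 0):
            raise PKValidationError(
                f"negative quantifiable concentration in {self.subject_id}/{self.analyte}"
            )
        if self.volume_dose <= 0:
            raise PKValidationError(f"volume_dose must be > 0, got {self.volume_dose}")

    @property
    def quantifiable(self) -> np.ndarray:
        """Boolean mask of non-BLQ observations."""
        return ~self.blq

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ContentTable:
    """Ingredient contents (µg/ml) for a set of preparation samples."""

    contents: pd.DataFrame  # rows = samples, columns = analytes

    def __post_init__(self) -> None:
        if (self.contents.to_numpy() < 0).any():
            raise PKValidationError("contents must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.contents.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.contents.columns)


def _detect_sep(path: Path) -> str:
    head = path.open("r", encoding="utf-8").readline()
    return "\t" if "\t" in head and "," not in head else ","


def read_pk_table(path: str | Path) -> list[PKProfile]:
    """Read a long-format concentration-time table into :class:`PKProfile`\\ s.

    The file must carry the columns ``subject_id, dose_group, dose_ml_per_kg,
    analyte, time_h, conc_ng_per_ml, blq`` (comma- or tab-separated).  Rows
    are grouped by (subject, analyte) and time-sorted; BLQ rows are retained
    with the flag set.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    missing = [c for c in PK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PKTableFormatError(f"missing column(s): {', '.join(missing)}")
    profiles: list[PKProfile] = []
    for (subject, analyte), grp in df.groupby(["subject_id", "analyte"], sort=True):
        grp = grp.sort_values("time_h")
        if grp["time_h"].duplicated().any():
            raise PKValidationError(
                f"duplicate sampling time for {subject}/{analyte}"
            )
        profiles.append(
            PKProfile(
                subject_id=str(subject),
                dose_group=str(grp["dose_group"].iloc[0]),
                volume_dose=float(grp["dose_ml_per_kg"].iloc[0]),
                analyte=str(analyte),
                times=grp["time_h"].to_numpy(float),
                concentrations=grp["conc_ng_per_ml"].to_numpy(float),
                blq=grp["blq"].to_numpy().astype(bool),
            )
        )
    return profiles


def profiles_to_frame(profiles: Iterable[PKProfile]) -> pd.DataFrame:
    """Flatten profiles into the long-format table layout."""
    rows = []
    for p in profiles:
        for t, c, b in zip(p.times, p.concentrations, p.blq):
            rows.append(
                (p.subject_id, p.dose_group, p.volume_dose, p.analyte, t, c, int(b))
            )
    return pd.DataFrame(rows, columns=list(PK_TABLE_COLUMNS))


def write_pk_table(profiles: Iterable[PKProfile], path: str | Path, sep: str = ",") -> None:
    """Write profiles as a long-format delimited table (UTF-8, '.' decimals)."""
    profiles_to_frame(profiles).to_csv(path, sep=sep, index=False)


def read_content_table(path: str | Path) -> ContentTable:
    """Read a sample x analyte ingredient-content table (µg/ml)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    return ContentTable(df.astype(float))


def mass_to_molar(conc_ug_per_ml: float | np.ndarray, molecular_weight: float):
    """Convert a mass concentration (µg/ml) to molarity (µM).

    µM = 1000 x (µg/ml) / (g/mol).  Rounding happens only at the
    presentation layer, never here.
    """
    if molecular_weight <= 0:
        raise PKValidationError(f"molecular_weight must be > 0, got {molecular_weight}")
    conc = np.asarray(conc_ug_per_ml, dtype=float)
    if np.any(conc < 0):
        raise PKValidationError("concentration must be >= 0")
    out = 1000.0 * conc / molecular_weight
    return float(out) if np.isscalar(conc_ug_per_ml) else out


def analyte_dose(volume_dose_ml_per_kg: float, content_ug_per_ml: float) -> float:
    """Mass dose (µg/kg) of one analyte delivered by a volume dose of the
    preparation: volume (ml/kg) x content (µg/ml)."""
    if volume_dose_ml_per_kg < 0 or content_ug_per_ml < 0:
        raise PKValidationError("dose inputs must be >= 0")
    return volume_dose_ml_per_kg * content_ug_per_ml
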