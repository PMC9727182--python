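"""Synthetic study-data generators.

Everything the pipeline consumes can be generated here with the statistical
structure the analysis assumes: IV-bolus plasma profiles with proportional
log-normal residual error and LOD censoring, MTT optical-density plates with
normal/model/treated/positive-control groups, ingredient-content tables, and
TMT-style protein abundance matrices with planted regulated sets.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .effect import EffectCurve
from .io import ContentTable, PKProfile, PKValidationError, analyte_dose
from . import published

__all__ = [
    "DispositionModel",
    "ErrorModel",
    "AnalyteDesign",
    "StudyDesign",
    "iv_bolus_concentration",
    "simulate_iv_profile",
    "simulate_cohort",
    "simulate_content_table",
    "simulate_od_plate",
    "simulate_protein_matrix",
    "default_study_design",
    "PK_SAMPLING_TIMES",
    "DOSE_GROUPS",
]

#: The study sampling schedule (h): 15 points from 2.4 min to 12 h post dose.
PK_SAMPLING_TIMES = np.array(
    [0.04, 0.083, 0.17, 0.25, 0.33, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0]
)

#: Volume dose (ml/kg) and group size of the three IV-bolus dose groups.
DOSE_GROUPS = {"low": (1.0, 4), "medium": (2.0, 3), "high": (4.0, 3)}


@dataclass(frozen=True)
class DispositionModel:
    """Linear mammillary disposition for an IV bolus.

    One compartment: C(t) = (D/V1)·exp(-CL/V1·t).  Two compartments: the
    standard bi-exponential solution parameterized by clearance, central and
    peripheral volumes and inter-compartment clearance Q.
    """

    clearance: float  # L/(h·kg)
    volumes: tuple[float, ...]  # L/kg, central first
    inter_compartment_clearance: float = 0.0  # L/(h·kg), 2-cpt only

    def __post_init__(self) -> None:
        if self.clearance <= 0 or any(v <= 0 for v in self.volumes):
            raise PKValidationError("clearance and volumes must be > 0")
        if len(self.volumes) not in (1, 2):
            raise PKValidationError("1 or 2 compartments supported")
        if len(self.volumes) == 2 and self.inter_compartment_clearance <= 0:
            raise PKValidationError("2-compartment model needs Q > 0")

    @property
    def n_compartments(self) -> int:
        return len(self.volumes)


@dataclass(frozen=True)
class ErrorModel:
    """Proportional log-normal residual error with LOD censoring.

    ``observed = true * exp(N(-s^2/2, s))`` with s chosen so the multiplicative
    noise has mean 1 and coefficient of variation ``proportional_cv``.
    Observations below ``lod`` (ng/ml) are zeroed and flagged BLQ.
    """

    proportional_cv: float = 0.15
    lod: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.lod < 0:
            raise PKValidationError("cv and lod must be >= 0")


def iv_bolus_concentration(model: DispositionModel, dose: float, times) -> np.ndarray:
    """Noise-free plasma concentration (ng/ml) at ``times`` (h).

    ``dose`` is in µg/kg; with volumes in L/kg the ratio dose/V is µg/L,
    i.e. ng/ml.
    """
    t = np.asarray(times, dtype=float)
    if model.n_compartments == 1:
        v = model.volumes[0]
        k = model.clearance / v
        return dose / v * np.exp(-k * t)
    v1, v2 = model.volumes
    k10 = model.clearance / v1
    k12 = model.inter_compartment_clearance / v1
    k21 = model.inter_compartment_clearance / v2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    c0 = dose / v1
    a = c0 * (alpha - k21) / (alpha - beta)
    b = c0 * (k21 - beta) / (alpha - beta)
    return a * np.exp(-alpha * t) + b * np.exp(-beta * t)


def simulate_iv_profile(
    model: DispositionModel,
    dose: float,
    times,
    error: ErrorModel,
    subject_id: str = "S1",
    dose_group: str = "high",
    volume_dose: float = 4.0,
) -> PKProfile:
    """Simulate one observed IV-bolus profile.

    True concentrations follow the closed-form disposition solution; the
    proportional error is applied per sample; values below the LOD are
    flagged BLQ and stored as 0.  The same ``error.seed`` always yields the
    same profile.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or np.any(np.diff(t) <= 0):
        raise PKValidationError("times must be non-empty and strictly increasing")
    if dose <= 0:
        raise PKValidationError("dose must be > 0")
    true_c = iv_bolus_concentration(model, dose, t)
    rng = np.random.default_rng(error.seed)
    if error.proportional_cv > 0:
        sigma = np.sqrt(np.log1p(error.proportional_cv**2))
        obs = true_c * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.size)
    else:
        obs = true_c.copy()
    blq = obs < error.lod
    obs = np.where(blq, 0.0, obs)
    return PKProfile(
        subject_id=subject_id,
        dose_group=dose_group,
        volume_dose=volume_dose,
        analyte="analyte",
        times=t,
        concentrations=obs,
        blq=blq,
    )


@dataclass(frozen=True)
class AnalyteDesign:
    """One analyte's disposition and its content in the preparation."""

    name: str
    model: DispositionModel
    content: float  # µg/ml in the injected preparation
    between_subject_cv: float = 0.30  # log-normal CV on CL and V


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: analytes, dose groups and the sampling schedule."""

    analytes: tuple[AnalyteDesign, ...]
    dose_groups: Mapping[str, tuple[float, int]] = field(
        default_factory=lambda: dict(DOSE_GROUPS)
    )
    times: np.ndarray = field(default_factory=lambda: PK_SAMPLING_TIMES.copy())
    residual_cv: float = 0.15
    lod: float = 0.5


def default_study_design(
    residual_cv: float = 0.15,
    between_subject_cv: float = 0.30,
    lod: float = 0.5,
) -> StudyDesign:
    """The study conditions: 6 analytes, doses 1/2/4 ml/kg with n = 4/3/3,
    15 sampling times from 0.04 to 12 h.

    Per-analyte clearance and terminal volume are set to the published
    high-dose group means, and each analyte's content in the preparation is
    back-solved from dose = CL x AUC0-inf at 4 ml/kg, so simulated exposures
    land on the published magnitudes.
    """
    means = published.table1_means()
    analytes = []
    for name in ("HSYA", "SYR", "p-CA", "SCU", "p-HBA", "RU"):
        row = means.loc[(name, "high")]
        cl, vz = float(row["cl"]), float(row["vz"])
        content = cl * float(row["auc_0_inf"]) / 4.0  # µg/kg per (ml/kg) = µg/ml
        analytes.append(
            AnalyteDesign(
                name=name,
                model=DispositionModel(clearance=cl, volumes=(vz,)),
                content=content,
                between_subject_cv=between_subject_cv,
            )
        )
    return StudyDesign(
        analytes=tuple(analytes), residual_cv=residual_cv, lod=lod
    )


def simulate_cohort(design: StudyDesign, seed: int) -> list[PKProfile]:
    """Simulate every subject x analyte profile of a study design.

    Between-subject variability is log-normal on clearance and volumes
    (shared across an animal's analytes only in seed lineage, not in value:
    each analyte's parameters are drawn independently, emulating unrelated
    disposition of chemically distinct ingredients).
    """
    rng = np.random.default_rng(seed)
    profiles: list[PKProfile] = []
    for group, (volume_dose, n) in design.dose_groups.items():
        if n < 1:
            raise PKValidationError(f"group {group!r} needs n >= 1")
        for j in range(n):
            subject = f"{group}-{j + 1}"
            for ad in design.analytes:
                model = ad.model
                if ad.between_subject_cv > 0:
                    sigma = np.sqrt(np.log1p(ad.between_subject_cv**2))
                    eta = rng.lognormal(-0.5 * sigma**2, sigma, size=2)
                    model = replace(
                        model,
                        clearance=model.clearance * eta[0],
                        volumes=tuple(v * eta[1] for v in model.volumes),
                    )
                dose = analyte_dose(volume_dose, ad.content)
                prof = simulate_iv_profile(
                    model,
                    dose,
                    design.times,
                    ErrorModel(design.residual_cv, design.lod,
                               seed=int(rng.integers(2**31))),
                    subject_id=subject,
                    dose_group=group,
                    volume_dose=volume_dose,
                )
                prof.analyte = ad.name
                profiles.append(prof)
    return profiles


def simulate_content_table(
    mean_percent: Mapping[str, float] | None = None,
    total_ug_per_ml: float = 416.0,
    n_samples: int = 15,
    cv: float = 0.0,
    seed: int = 0,
) -> ContentTable:
    """Sample x analyte content table (µg/ml) around given mean proportions.

    Defaults reproduce the published normalized composition of the
    preparation (HSYA 62%, uridine 13.5%, SYR 11.0%, p-CA 9.0%, minor
    ingredients sharing the remainder) at a realistic total of the 11
    quantified ingredients.  ``cv=0`` gives identical samples.
    """
    if mean_percent is None:
        mean_percent = published.COMPOSITION_MEAN_PERCENT
    names = list(mean_percent)
    base = np.array([mean_percent[k] for k in names]) / 100.0 * total_ug_per_ml
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_samples):
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv**2))
            rows.append(base * rng.lognormal(-0.5 * sigma**2, sigma, size=len(base)))
        else:
            rows.append(base.copy())
    idx = [f"S{i // 5 + 1}-{i % 5 + 1}" for i in range(n_samples)]
    return ContentTable(pd.DataFrame(rows, index=idx, columns=names))


def simulate_od_plate(
    protection_curve: EffectCurve,
    od_normal: float,
    od_model: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 4,
    positive_rate: float | None = None,
) -> pd.DataFrame:
    """MTT plate for one analyte: OD570 by group and replicate.

    Treated-group mean OD is ``od_model + rate/100 * (od_normal - od_model)``
    with the rate read off ``protection_curve`` at each concentration (µM);
    Gaussian well noise of ``noise_sd`` OD units is added.  A positive
    control group is included when ``positive_rate`` is given.
    """
    if od_normal <= od_model or od_model < 0:
        raise PKValidationError("need od_normal > od_model >= 0")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, float, int, float]] = []

    def add(group: str, conc: float, mean_od: float) -> None:
        for r in range(n_replicates):
            od = mean_od + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((group, conc, r + 1, od))

    add("normal", np.nan, od_normal)
    add("model", np.nan, od_model)
    span = od_normal - od_model
    for conc in concentrations:
        rate = float(
            np.interp(conc, protection_curve.concentrations, protection_curve.rates)
        )
        add(f"{protection_curve.analyte}@{conc:g}uM", float(conc),
            od_model + rate / 100.0 * span)
    if positive_rate is not None:
        add("positive", np.nan, od_model + positive_rate / 100.0 * span)
    return pd.DataFrame(rows, columns=["group", "conc_uM", "replicate", "od570"])


def simulate_protein_matrix(
    n_proteins: int,
    groups: Mapping[str, int],
    planted_up: Sequence[str] = (),
    planted_down: Sequence[str] = (),
    fc: float = 1.5,
    cv: float = 0.1,
    seed: int = 0,
    contrast_group: str | None = None,
) -> pd.DataFrame:
    """Protein x sample abundance matrix with planted regulated sets.

    Baseline abundances are log-normal across proteins; within-group
    replicate scatter is log-normal with coefficient of variation ``cv``.
    Proteins in ``planted_up`` (``planted_down``) are multiplied (divided)
    by ``fc`` in ``contrast_group`` (default: the last group listed).
    """
    if fc < 1:
        raise PKValidationError("fc must be >= 1")
    up, down = set(planted_up), set(planted_down)
    if up & down:
        raise PKValidationError("planted_up and planted_down must be disjoint")
    names = [f"P{i + 1:04d}" for i in range(n_proteins)]
    unknown = (up | down) - set(names)
    if unknown:
        raise PKValidationError(f"planted proteins not in matrix: {sorted(unknown)}")
    if contrast_group is None:
        contrast_group = list(groups)[-1]
    if contrast_group not in groups:
        raise PKValidationError(f"unknown contrast group {contrast_group!r}")
    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(mean=np.log(1e6), sigma=1.0, size=n_proteins)
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    cols, data = [], []
    for group, n in groups.items():
        shift = np.ones(n_proteins)
        if group == contrast_group:
            for i, name in enumerate(names):
                if name in up:
                    shift[i] = fc
                elif name in down:
                    shift[i] = 1.0 / fc
        for r in range(n):
            cols.append(f"{group}_{r + 1}")
            noise = (
                rng.lognormal(-0.5 * sigma**2, sigma, size=n_proteins)
                if sigma > 0
                else 1.0
            )
            data.append(baseline * shift * noise)
    return pd.DataFrame(np.column_stack(data), index=names, columns=cols)
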