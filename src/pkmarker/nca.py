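"""Non-compartmental analysis of IV-bolus concentration-time profiles.

Implements terminal-slope (lambda-z) estimation by exhaustive suffix-window
search on the log-linear tail, trapezoidal AUC/AUMC (linear or
linear-up/log-down), and the derived parameter set t1/2, Cmax, AUC0-t,
AUC0-inf, AUMC, MRT, CL and Vz.

Conventions
-----------
* No back-extrapolation to t=0: areas start at the first observed time.
* AUC0-inf adds C_last(observed)/lambda_z to AUC0-t.
* BLQ handling: leading BLQ observations enter the trapezoid as zeros,
  embedded and trailing BLQ observations are dropped.
* Units: dose in µg/kg, concentrations in ng/ml (= µg/L), times in h, so
  CL = dose/AUC0-inf comes out directly in L/(h·kg) and Vz = CL/lambda_z
  in L/kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PKProfile, PKValidationError

__all__ = [
    "LambdaZFit",
    "NCAResult",
    "TerminalPhaseError",
    "fit_lambda_z",
    "auc_trapezoid",
    "aumc_trapezoid",
    "compute_nca",
    "nca_table",
    "nca_group_summary",
]

NCA_PARAMETERS = [
    "t_half", "c_max", "auc_0_t", "auc_0_inf", "vz", "cl", "mrt_0_t", "mrt_0_inf",
]

_R2_TIE = 1e-4  # adjusted-R2 ties resolved toward the larger window


class TerminalPhaseError(ValueError):
    """The terminal elimination phase cannot be estimated from this profile."""


@dataclass(frozen=True)
class LambdaZFit:
    """Accepted terminal-slope fit.

    ``lambda_z`` is the negative slope of ln(C) vs t over the last
    ``n_points`` quantifiable observations starting at ``t_first``.
    """

    lambda_z: float  # 1/h
    n_points: int
    r2_adjusted: float
    t_first: float  # h
    c_last_observed: float  # ng/ml
    t_last: float  # h


@dataclass
class NCAResult:
    """Non-compartmental parameter set for one profile.

    Terminal-phase parameters are NaN when lambda-z is inestimable but the
    profile still has quantifiable observations (partial output).
    """

    subject_id: str
    dose_group: str
    analyte: str
    dose: float  # µg/kg
    t_half: float = math.nan  # h
    c_max: float = math.nan  # ng/ml
    t_max: float = math.nan  # h
    auc_0_t: float = math.nan  # h·ng/ml
    auc_0_inf: float = math.nan
    aumc_0_t: float = math.nan  # h^2·ng/ml
    aumc_0_inf: float = math.nan
    mrt_0_t: float = math.nan  # h
    mrt_0_inf: float = math.nan
    vz: float = math.nan  # L/kg
    cl: float = math.nan  # L/(h·kg)
    extrapolated_fraction: float = math.nan
    lambda_z_fit: LambdaZFit | None = None


def _quantifiable_tail(profile: PKProfile) -> tuple[np.ndarray, np.ndarray]:
    """Times and concentrations usable in the trapezoid, after BLQ rules."""
    t, c, blq = profile.times, profile.concentrations, profile.blq
    quant = ~blq
    if not quant.any():
        raise TerminalPhaseError(
            f"all observations BLQ for {profile.subject_id}/{profile.analyte}"
        )
    first_q = int(np.argmax(quant))
    last_q = len(quant) - 1 - int(np.argmax(quant[::-1]))
    # leading BLQ kept as zeros; embedded BLQ dropped; trailing BLQ dropped
    keep = np.zeros(len(t), dtype=bool)
    keep[: first_q + 1] = True
    keep[first_q : last_q + 1] = quant[first_q : last_q + 1]
    return t[keep], c[keep]


def _loglinear_ols(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and adjusted R^2 of an OLS line through (t, ln C)."""
    n = len(t)
    slope, intercept = np.polyfit(t, logc, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((logc - fitted) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-24 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(slope), float(intercept), float(r2_adj)


def fit_lambda_z(profile: PKProfile, min_points: int = 3) -> LambdaZFit:
    """Estimate the terminal elimination rate constant of one profile.

    Candidate windows are all suffixes (size >= ``min_points``) of the
    quantifiable tail; for profiles whose maximum is not at the first sample
    the Cmax point is excluded from candidates.  The window maximizing
    adjusted R^2 wins; ties closer than 1e-4 go to the larger window.

    Raises
    ------
    TerminalPhaseError
        Fewer than ``min_points`` usable points, or no window with a
        negative slope.
    """
    quant = profile.quantifiable & (profile.concentrations > 0)
    t = profile.times[quant]
    c = profile.concentrations[quant]
    if len(t) == 0:
        raise TerminalPhaseError(
            f"all observations BLQ for {profile.subject_id}/{profile.analyte}"
        )
    i_max = int(np.argmax(c))
    if i_max > 0:  # not IV-bolus-shaped: terminal phase starts after Cmax
        t, c = t[i_max + 1 :], c[i_max + 1 :]
    if len(t) < min_points:
        raise TerminalPhaseError(
            f"only {len(t)} usable terminal points for "
            f"{profile.subject_id}/{profile.analyte} (need >= {min_points})"
        )
    logc = np.log(c)
    best: tuple[float, int, float] | None = None  # (r2_adj, n, slope)
    for n in range(min_points, len(t) + 1):
        slope, _, r2_adj = _loglinear_ols(t[-n:], logc[-n:])
        if slope >= 0:
            continue
        if best is None or r2_adj > best[0] + _R2_TIE or (
            abs(r2_adj - best[0]) <= _R2_TIE and n > best[1]
        ):
            best = (r2_adj, n, slope)
    if best is None:
        raise TerminalPhaseError(
            f"no negative terminal slope for {profile.subject_id}/{profile.analyte}"
        )
    r2_adj, n, slope = best
    return LambdaZFit(
        lambda_z=-slope,
        n_points=n,
        r2_adjusted=r2_adj,
        t_first=float(t[-n]),
        c_last_observed=float(c[-1]),
        t_last=float(t[-1]),
    )


def _segment_areas(t: np.ndarray, c: np.ndarray, rule: str):
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    t1, t2 = t[:-1], t[1:]
    lin_auc = 0.5 * (c1 + c2) * dt
    lin_aumc = 0.5 * (t1 * c1 + t2 * c2) * dt
    if rule == "linear":
        return lin_auc, lin_aumc
    if rule != "log-down":
        raise ValueError(f"unknown rule {rule!r}; use 'linear' or 'log-down'")
    down = (c2 < c1) & (c2 > 0)
    auc = lin_auc.copy()
    aumc = lin_aumc.copy()
    if down.any():
        k = np.log(c1[down] / c2[down]) / dt[down]
        auc[down] = (c1[down] - c2[down]) / k
        aumc[down] = (t1[down] * c1[down] - t2[down] * c2[down]) / k + (
            c1[down] - c2[down]
        ) / k**2
    return auc, aumc


def auc_trapezoid(times, concs, rule: str = "linear") -> float:
    """Area under the concentration-time curve by the trapezoidal rule.

    ``rule='log-down'`` applies the logarithmic trapezoid on strictly
    decreasing positive segments (linear-up/log-down).  A single point has
    zero area.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise PKValidationError("times must be strictly increasing")
    if len(t) < 2:
        return 0.0
    auc, _ = _segment_areas(t, c, rule)
    return float(np.sum(auc))


def aumc_trapezoid(times, concs, rule: str = "linear") -> float:
    """Area under the first-moment (t·C) curve, same rules as AUC."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise PKValidationError("times must be strictly increasing")
    if len(t) < 2:
        return 0.0
    _, aumc = _segment_areas(t, c, rule)
    return float(np.sum(aumc))


def compute_nca(
    profile: PKProfile,
    dose: float,
    rule: str = "linear",
    min_points: int = 3,
) -> NCAResult:
    """Full non-compartmental parameter set for one profile.

    Parameters
    ----------
    profile
        Concentration-time course (ng/ml vs h).
    dose
        Analyte mass dose in µg/kg (> 0).
    rule
        Trapezoid rule, ``'linear'`` (default) or ``'log-down'``.

    Returns a partial result (terminal parameters NaN) when lambda-z is
    inestimable; raises :class:`TerminalPhaseError` only when every
    observation is BLQ.
    """
    if dose <= 0:
        raise PKValidationError(f"dose must be > 0, got {dose}")
    t, c = _quantifiable_tail(profile)
    res = NCAResult(
        subject_id=profile.subject_id,
        dose_group=profile.dose_group,
        analyte=profile.analyte,
        dose=dose,
    )
    quant_c = profile.concentrations[profile.quantifiable]
    quant_t = profile.times[profile.quantifiable]
    i = int(np.argmax(quant_c))
    res.c_max = float(quant_c[i])
    res.t_max = float(quant_t[i])
    res.auc_0_t = auc_trapezoid(t, c, rule)
    res.aumc_0_t = aumc_trapezoid(t, c, rule)
    if res.auc_0_t > 0:
        res.mrt_0_t = res.aumc_0_t / res.auc_0_t
    try:
        fit = fit_lambda_z(profile, min_points=min_points)
    except TerminalPhaseError:
        return res
    lz = fit.lambda_z
    res.lambda_z_fit = fit
    res.t_half = math.log(2) / lz
    c_last, t_last = fit.c_last_observed, fit.t_last
    res.auc_0_inf = res.auc_0_t + c_last / lz
    res.aumc_0_inf = res.aumc_0_t + c_last * t_last / lz + c_last / lz**2
    res.mrt_0_inf = res.aumc_0_inf / res.auc_0_inf
    res.cl = dose / res.auc_0_inf  # µg/kg / (h·µg/L) = L/(h·kg)
    res.vz = res.cl / lz
    res.extrapolated_fraction = 1.0 - res.auc_0_t / res.auc_0_inf
    return res


def nca_table(results) -> pd.DataFrame:
    """Per-subject NCA results as a tidy frame (one row per profile)."""
    rows = []
    for r in results:
        rows.append(
            {
                "subject_id": r.subject_id,
                "dose_group": r.dose_group,
                "analyte": r.analyte,
                "dose": r.dose,
                "t_half": r.t_half,
                "c_max": r.c_max,
                "t_max": r.t_max,
                "auc_0_t": r.auc_0_t,
                "auc_0_inf": r.auc_0_inf,
                "aumc_0_t": r.aumc_0_t,
                "aumc_0_inf": r.aumc_0_inf,
                "mrt_0_t": r.mrt_0_t,
                "mrt_0_inf": r.mrt_0_inf,
                "vz": r.vz,
                "cl": r.cl,
                "extrapolated_fraction": r.extrapolated_fraction,
            }
        )
    return pd.DataFrame(rows)


def nca_group_summary(results) -> pd.DataFrame:
    """Mean +/- SD of the reported parameters per analyte x dose group.

    Mirrors the usual publication layout; inestimable cells propagate as
    NaN (printed as a dash at the presentation layer).
    """
    df = nca_table(results)
    out = df.groupby(["analyte", "dose_group"])[NCA_PARAMETERS].agg(["mean", "std"])
    return out
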