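"""Published study inputs for the safflower-injection PK-marker analysis.

The original rat concentration-time and OD plate data are not deposited, so
the printed summary tables of the source study act as pipeline *inputs*:
Table-1 non-compartmental parameters (mean +/- SD per dose group), the
ingredient composition of the preparation, the measured effect AUCs for the
two protective ingredients, and the qualitative criterion annotations behind
the final marker call.  Everything downstream is computed from these.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "table1_means",
    "table1_sds",
    "COMPOSITION_MEAN_PERCENT",
    "EFFECT_AUC_PCT_UM",
    "CMAX_HIGH_UG_PER_ML",
    "DETECTION_PATTERN",
    "CVD_RELEVANT",
    "EFFECT_VALIDATED",
    "PROTECTION_AT_CMAX_PCT",
]

_TABLE1_COLUMNS = [
    "t_half", "c_max", "auc_0_t", "auc_0_inf", "vz", "cl", "mrt_0_t", "mrt_0_inf",
]

# (analyte, dose group) -> [t1/2 h, Cmax ng/ml, AUC0-t h·ng/ml, AUC0-inf h·ng/ml,
#                           Vd L/kg, Cl L/(h·kg), MRT0-t h, MRT0-inf h]
_TABLE1_MEAN = {
    ("SYR", "low"): [0.25, 259.50, 100.67, 115.88, 0.21, 0.69, 0.27, 0.38],
    ("SYR", "medium"): [0.61, 465.33, 363.24, 367.67, 0.31, 0.34, 0.69, 0.75],
    ("SYR", "high"): [0.53, 925.33, 585.69, 591.71, 0.31, 0.41, 0.67, 0.71],
    ("HSYA", "low"): [0.47, 2624.50, 2479.11, 2490.30, 0.09, 0.13, 0.76, 0.78],
    ("HSYA", "medium"): [0.64, 5628.33, 5074.18, 5461.77, 0.09, 0.10, 0.79, 0.97],
    ("HSYA", "high"): [0.46, 14077.33, 11015.37, 11453.34, 0.06, 0.09, 0.70, 0.78],
    ("p-CA", "low"): [0.08, 305.00, 62.45, 67.71, 0.11, 1.21, 0.10, 0.12],
    ("p-CA", "medium"): [0.22, 715.00, 265.09, 277.26, 0.13, 0.40, 0.27, 0.33],
    ("p-CA", "high"): [0.21, 1255.00, 432.92, 469.10, 0.14, 0.45, 0.25, 0.32],
    ("SCU", "medium"): [2.58, 162.20, 89.76, 104.73, 0.05, 0.01, 1.46, 2.90],
    ("SCU", "high"): [2.84, 327.33, 305.74, 358.05, 0.03, 0.01, 1.57, 2.96],
    ("p-HBA", "medium"): [0.48, 44.67, 20.15, 23.41, 0.35, 0.53, 0.43, 0.67],
    ("p-HBA", "high"): [0.39, 74.33, 35.19, 44.04, 0.34, 0.99, 0.32, 0.53],
    ("RU", "high"): [0.24, 39.33, 12.38, 15.10, 0.30, 0.86, 0.22, 0.36],
}

_TABLE1_SD = {
    ("SYR", "low"): [0.09, 59.35, 57.37, 70.51, 0.07, 0.43, 0.10, 0.16],
    ("SYR", "medium"): [0.25, 42.92, 81.55, 78.73, 0.20, 0.07, 0.07, 0.14],
    ("SYR", "high"): [0.23, 38.55, 94.42, 96.56, 0.11, 0.07, 0.21, 0.23],
    ("HSYA", "low"): [0.07, 660.17, 1312.76, 1317.76, 0.04, 0.07, 0.19, 0.19],
    ("HSYA", "medium"): [0.08, 405.14, 328.93, 202.42, 0.01, 0.00, 0.14, 0.06],
    ("HSYA", "high"): [0.12, 17.21, 1025.71, 668.38, 0.02, 0.01, 0.09, 0.11],
    ("p-CA", "low"): [0.05, 147.31, 50.04, 57.20, 0.03, 0.76, 0.05, 0.07],
    ("p-CA", "medium"): [0.06, 85.75, 89.73, 84.05, 0.07, 0.13, 0.03, 0.01],
    ("p-CA", "high"): [0.05, 69.07, 44.53, 38.10, 0.03, 0.04, 0.04, 0.04],
    ("SCU", "medium"): [1.84, 17.41, 21.01, 31.46, 0.02, 0.01, 0.64, 2.42],
    ("SCU", "high"): [1.19, 60.05, 12.47, 33.97, 0.01, 0.00, 0.68, 1.49],
    ("p-HBA", "medium"): [0.11, 5.13, 4.40, 5.21, 0.04, 0.11, 0.04, 0.11],
    ("p-HBA", "high"): [0.35, 2.52, 31.15, 45.17, 0.09, 0.66, 0.25, 0.53],
    ("RU", "high"): [0.04, 1.53, 1.37, 2.23, 0.02, 0.13, 0.03, 0.06],
}


def _frame(d: dict) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(d.keys(), names=["analyte", "dose_group"])
    return pd.DataFrame(list(d.values()), index=idx, columns=_TABLE1_COLUMNS)


def table1_means() -> pd.DataFrame:
    """Mean NCA parameters of the six quantified ingredients per dose group.

    Dose groups left out of the index (e.g. SCU/p-HBA low, RU low and medium)
    were inestimable in the original assay.
    """
    return _frame(_TABLE1_MEAN)


def table1_sds() -> pd.DataFrame:
    """Between-animal SDs matching :func:`table1_means`."""
    return _frame(_TABLE1_SD)


#: Normalized mean content (%) of the 11 quantified ingredients of the
#: preparation; the seven minor ingredients share the ~4.5% remainder.
COMPOSITION_MEAN_PERCENT = {
    "HSYA": 62.0,
    "uridine": 13.5,
    "SYR": 11.0,
    "p-CA": 9.0,
    "SCU": 1.2,
    "p-HBA": 0.9,
    "RU": 0.8,
    "adenosine": 0.7,
    "cytidine": 0.5,
    "quercetin": 0.25,
    "trans-cinnamic acid": 0.15,
}

#: Measured average area under the protection-rate vs concentration curve
#: (%·µM) within each ingredient's observed plasma concentration range.
EFFECT_AUC_PCT_UM = {"HSYA": 473.19, "SYR": 12.18}

#: Mean maximum plasma concentrations (µg/ml) after the 4 ml/kg dose.
CMAX_HIGH_UG_PER_ML = {
    "HSYA": 14.07,
    "SYR": 0.93,
    "p-CA": 1.25,
    "SCU": 0.327,
    "p-HBA": 0.074,
    "RU": 0.039,
}

#: Lowest dose group at which each ingredient's terminal phase was estimable.
DETECTION_PATTERN = {
    "HSYA": "low",
    "SYR": "low",
    "p-CA": "low",
    "SCU": "medium",
    "p-HBA": "medium",
    "RU": "high",
}

#: Ingredients predicted highly relevant to cardiovascular disease by the
#: target-fishing / disease-ontology arm of the study (external annotation).
CVD_RELEVANT = frozenset({"HSYA", "SYR", "RU"})

#: Ingredients whose cardiomyocyte protection was experimentally confirmed.
EFFECT_VALIDATED = frozenset({"HSYA", "SYR"})

#: Protection rate (%) observed at each ingredient's high-dose Cmax in the
#: H2O2-injured H9c2 assay; non-protective ingredients sit at ~0.
PROTECTION_AT_CMAX_PCT = {"HSYA": 26.0, "SYR": 10.0}
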