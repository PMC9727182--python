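"""Differential-protein filtering of quantified abundance matrices.

A protein is called up-regulated in the contrast group when its raw-mean
fold change is >= 1.5 and the two-sample t-test on log2 abundances gives
p < 0.05; down-regulated when the fold change is <= 1/1.5 at the same
significance.  No multiple-testing correction is applied by default (a
Benjamini-Hochberg option exists and departs from the original rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import PKValidationError

__all__ = ["DEPResult", "dep_filter"]


@dataclass
class DEPResult:
    """Per-protein fold changes, p-values and up/down/none calls."""

    table: pd.DataFrame  # columns: fold_change, p_value, call
    reference_group: str
    contrast_group: str

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())

    @property
    def up(self) -> list[str]:
        return list(self.table.index[self.table["call"] == "up"])

    @property
    def down(self) -> list[str]:
        return list(self.table.index[self.table["call"] == "down"])


def dep_filter(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    reference_group: str,
    contrast_group: str,
    fc_up: float = 1.5,
    alpha: float = 0.05,
    equal_var: bool = True,
    bh_correct: bool = False,
) -> DEPResult:
    """Filter a protein x sample matrix for differential expression.

    Parameters
    ----------
    matrix
        Positive abundances, proteins as rows, samples as columns.
    groups
        Sample name -> group label.
    reference_group, contrast_group
        Labels defining the comparison; fold change is contrast/reference.
    fc_up
        Up-regulation threshold (>= 1); down uses 1/fc_up.
    alpha
        Raw p-value threshold.
    equal_var
        Student (True, default) vs Welch t-test on log2 abundances.
    bh_correct
        Apply Benjamini-Hochberg to the p-values before thresholding.
        This departs from the original raw-p rule and is off by default.
    """
    ref_cols = [s for s, g in groups.items() if g == reference_group]
    con_cols = [s for s, g in groups.items() if g == contrast_group]
    for label, cols in ((reference_group, ref_cols), (contrast_group, con_cols)):
        if len(cols) < 2:
            raise PKValidationError(f"group {label!r} needs >= 2 replicates")
        missing = [c for c in cols if c not in matrix.columns]
        if missing:
            raise PKValidationError(f"samples not in matrix: {missing}")
    ref = matrix[ref_cols].to_numpy(float)
    con = matrix[con_cols].to_numpy(float)
    if np.any(ref <= 0) or np.any(con <= 0):
        raise PKValidationError("abundances must be positive")
    fold = con.mean(axis=1) / ref.mean(axis=1)
    t_res = stats.ttest_ind(np.log2(con), np.log2(ref), axis=1, equal_var=equal_var)
    p = np.asarray(t_res.pvalue)
    p = np.where(np.isnan(p), 1.0, p)  # zero within-group variance, equal means
    p_thresh = p
    if bh_correct:
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty_like(p)
        q[order] = np.clip(ranked, 0, 1)
        p_thresh = q
    call = np.where(
        (p_thresh < alpha) & (fold >= fc_up),
        "up",
        np.where((p_thresh < alpha) & (fold <= 1.0 / fc_up), "down", "none"),
    )
    table = pd.DataFrame(
        {"fold_change": fold, "p_value": p, "call": call}, index=matrix.index
    )
    if bh_correct:
        table["q_value"] = p_thresh
    return DEPResult(table, reference_group, contrast_group)
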