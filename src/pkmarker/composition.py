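"""Percent-composition normalization of ingredient-content tables.

Each preparation sample's ingredient contents (µg/ml) are rescaled to
percent of that sample's total; mean percents across samples rank the
ingredients and define the "major component" set at a cumulative-percent
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ContentTable, PKValidationError

__all__ = ["CompositionResult", "normalize_contents", "major_components"]


@dataclass
class CompositionResult:
    """Percent composition of a preparation across samples."""

    percent: pd.DataFrame  # sample x analyte, rows sum to 100
    mean_percent: pd.Series  # per analyte, sums to 100
    ranking: list[str]  # analytes by descending mean percent

    def cumulative_percent(self) -> pd.Series:
        """Cumulative mean percent along the ranking."""
        return self.mean_percent.loc[self.ranking].cumsum()


def normalize_contents(table: ContentTable) -> CompositionResult:
    """Normalize a sample x analyte content table to percent composition.

    percent_ij = 100 * content_ij / sum_j content_ij.  Mean percents are
    pooled across all samples; ties in the ranking break lexicographically.
    """
    df = table.contents
    totals = df.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise PKValidationError(f"sample(s) with zero total content: {list(zero.index)}")
    percent = df.div(totals, axis=0) * 100.0
    mean_percent = percent.mean(axis=0)
    order = sorted(mean_percent.index, key=lambda a: (-mean_percent[a], a))
    return CompositionResult(percent=percent, mean_percent=mean_percent, ranking=order)


def major_components(result: CompositionResult, cumulative_threshold: float = 95.0) -> list[str]:
    """Smallest prefix of the ranking whose cumulative mean percent reaches
    the threshold (always at least one analyte)."""
    cum = result.cumulative_percent()
    out: list[str] = []
    for analyte, c in cum.items():
        out.append(analyte)
        if c >= cumulative_threshold:
            break
    return out
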