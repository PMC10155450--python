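"""Descriptive outputs: frequency counts, the symptom-count-stratified
co-occurrence table, and the filtered top-correlates table.

The stratified report buckets narratives by how many symptoms they mention
(0, 1, 2, 3, "4 or more") and, per stratum, counts how many mention the
index symptom; it is computed on the PRE-row-cleaning matrix (the
zero-symptom stratum must still be present) but after column merging.
Percentages are rendered to two decimals, rounding half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .screen import CorrelationResult, ScreenConfig, round_half_away

__all__ = [
    "StratumRow",
    "StratifiedReport",
    "stratified_report",
    "frequency_table",
    "top_correlates",
    "plot_frequency",
]

_STRATUM_LABELS = ("0", "1", "2", "3", "4 or more")


@dataclass(frozen=True)
class StratumRow:
    label: str
    n_narratives: int
    n_with_index: int
    percentage: float  # 100 * n_with_index / n_narratives, two decimals


@dataclass(frozen=True)
class StratifiedReport:
    """Index-symptom co-occurrence stratified by symptoms-per-narrative."""

    index_symptom: str
    strata: tuple[StratumRow, ...]
    total: StratumRow
    empty_strata: tuple[str, ...]  # labels rendered with percentage 0, flagged

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "Total number of symptoms reported": s.label,
                "Total Narratives": s.n_narratives,
                "Mentioned index symptom": s.n_with_index,
                "Percentage": s.percentage,
            }
            for s in (*self.strata, self.total)
        ]
        return pd.DataFrame(rows)

    def as_text(self) -> str:
        return self.as_frame().to_string(index=False)


def stratified_report(matrix: pd.DataFrame, index_symptom: str) -> StratifiedReport:
    """Bucket rows by row sum (0,1,2,3,>=4) and count index-symptom mentions.

    ``matrix`` must be the pre-row-cleaning matrix: zero-symptom rows
    included, columns already merged to canonicals.
    """
    if index_symptom not in matrix.columns:
        raise ValueError(f"index symptom {index_symptom!r} not in matrix columns")
    row_sums = matrix.sum(axis=1).to_numpy()
    index_col = matrix[index_symptom].to_numpy()
    strata: list[StratumRow] = []
    empty: list[str] = []
    for label in _STRATUM_LABELS:
        if label == "4 or more":
            mask = row_sums >= 4
        else:
            mask = row_sums == int(label)
        n = int(mask.sum())
        n_idx = int(index_col[mask].sum())
        pct = round_half_away(100.0 * n_idx / n) if n else 0.0
        if n == 0:
            empty.append(label)
        strata.append(StratumRow(label, n, n_idx, pct))
    n_total = int(matrix.shape[0])
    n_idx_total = int(index_col.sum())
    total = StratumRow(
        "Total",
        n_total,
        n_idx_total,
        round_half_away(100.0 * n_idx_total / n_total) if n_total else 0.0,
    )
    assert sum(s.n_narratives for s in strata) == total.n_narratives
    assert sum(s.n_with_index for s in strata) == total.n_with_index
    return StratifiedReport(index_symptom, tuple(strata), total, tuple(empty))


def frequency_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """(symptom, count) column sums, descending by count, ties alphabetical."""
    counts = matrix.sum(axis=0)
    df = pd.DataFrame(
        {"symptom": counts.index, "count": counts.to_numpy().astype(int)}
    )
    return df.sort_values(
        ["count", "symptom"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def top_correlates(
    results: Sequence[CorrelationResult], config: ScreenConfig = ScreenConfig()
) -> list[CorrelationResult]:
    """Subset of screen results in the small band (both signs), order preserved.

    The companion full list is the ``results`` sequence itself — callers
    writing reports should always write both.
    """
    return [res for res in results if res.band == "small"]


def plot_frequency(matrix: pd.DataFrame, path, top: int = 20) -> None:
    """Horizontal bar chart of the most frequently reported symptoms."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = frequency_table(matrix).head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(table) + 1.2))
    ax.barh(table["symptom"], table["count"], color="#4878a8")
    ax.set_xlabel("narratives mentioning the symptom")
    ax.set_title(f"Most frequently reported symptoms (n = {matrix.shape[0]})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
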