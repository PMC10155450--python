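"""One-hot encode symptom sets into a patient x symptom binary matrix and clean it.

The binary matrix is a :class:`pandas.DataFrame` with patient ids as the
index, canonical symptom names as columns, and {0,1} cells — 1 means the
patient reported that symptom at least once, regardless of how many times
it was mentioned.

Cleaning applies, in order:

1. merge variant-named columns into their canonical (logical OR of cells,
   e.g. ``sad`` and ``sadness`` clump into one column);
2. drop blacklisted (non-symptom) columns;
3. drop rows with no symptoms at all;
4. drop exact duplicate records, keeping the first.

Duplicates are detected on raw narrative text when the texts are supplied;
deduplicating on the binary pattern alone would collapse the many distinct
patients who happen to report the same symptom combination, so it is never
done.  Without texts, a record is a duplicate only if both its pattern and
its patient id repeat.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .extraction import NarrativeRecord, SymptomSet
from .lexicon import SymptomLexicon

__all__ = [
    "CleaningReport",
    "build_matrix",
    "clean_matrix",
    "read_matrix",
    "write_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleaningReport:
    """Row/column accounting for one cleaning pass."""

    n_input_rows: int
    n_zero_symptom_rows_removed: int
    n_duplicate_rows_removed: int
    n_columns_merged: int
    n_columns_blacklisted: int
    n_output_rows: int
    n_output_columns: int

    def __post_init__(self) -> None:
        expected = (
            self.n_input_rows
            - self.n_zero_symptom_rows_removed
            - self.n_duplicate_rows_removed
        )
        if self.n_output_rows != expected:
            raise ValueError(
                f"inconsistent cleaning report: {self.n_output_rows} != "
                f"{self.n_input_rows} - {self.n_zero_symptom_rows_removed} - "
                f"{self.n_duplicate_rows_removed}"
            )

    def as_dict(self) -> dict[str, int]:
        return asdict(self)

    def as_text(self) -> str:
        return "\n".join(f"{k}: {v}" for k, v in self.as_dict().items())


def build_matrix(
    sets: Sequence[SymptomSet],
    lexicon: SymptomLexicon | None = None,
    *,
    all_columns: bool = False,
) -> pd.DataFrame:
    """One-hot encode symptom sets (row per patient, column per canonical symptom).

    Columns are the canonicals reported by at least one patient, sorted; with
    ``all_columns=True`` every lexicon canonical gets a column even if never
    reported.
    """
    if all_columns:
        if lexicon is None:
            raise ValueError("all_columns=True requires a lexicon")
        columns = list(lexicon.canonicals)
    else:
        columns = sorted({s for ss in sets for s in ss.symptoms})
    if lexicon is not None:
        unknown = {s for ss in sets for s in ss.symptoms} - set(lexicon.canonicals)
        if unknown:
            raise ValueError(f"symptoms not in lexicon: {sorted(unknown)}")
    data = np.zeros((len(sets), len(columns)), dtype=np.int8)
    col_index = {c: j for j, c in enumerate(columns)}
    for i, ss in enumerate(sets):
        for s in ss.symptoms:
            data[i, col_index[s]] = 1
    return pd.DataFrame(
        data, index=pd.Index([ss.patient_id for ss in sets], name="patient_id"),
        columns=columns,
    )


def clean_matrix(
    matrix: pd.DataFrame,
    lexicon: SymptomLexicon,
    raw_records: Sequence[NarrativeRecord] | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the four cleaning rules; returns the cleaned matrix and its report."""
    n_input_rows, n_input_cols = matrix.shape

    # (1) merge variant columns into their canonical (OR semantics)
    form_map = lexicon.form_to_canonical
    target: dict[str, str] = {}
    for col in matrix.columns:
        if col in lexicon.entries or col in lexicon.blacklist:
            target[col] = col
        elif col in form_map:
            target[col] = form_map[col]
        else:
            warnings.warn(
                f"column {col!r} not in lexicon; kept as its own canonical",
                stacklevel=2,
            )
            target[col] = col
    merged = (matrix.T.groupby([target[c] for c in matrix.columns]).max()).T
    # preserve first-appearance order of the merge targets
    order = list(dict.fromkeys(target[c] for c in matrix.columns))
    merged = merged[order]
    n_columns_merged = n_input_cols - merged.shape[1]

    # (2) drop blacklisted columns
    blacklisted = [c for c in merged.columns if c in lexicon.blacklist]
    merged = merged.drop(columns=blacklisted)

    # (3) drop rows with no symptoms
    nonzero = merged.sum(axis=1) > 0
    n_zero_removed = int((~nonzero).sum())
    merged = merged.loc[nonzero]

    # (4) drop exact duplicate records, keeping the first
    if raw_records is not None:
        texts = {r.patient_id: r.text for r in raw_records}
        missing = [pid for pid in merged.index if pid not in texts]
        if missing:
            raise ValueError(f"raw_records missing ids: {missing[:5]}")
        keys = pd.Series([texts[pid] for pid in merged.index], index=merged.index)
        dup = keys.duplicated(keep="first")
    else:
        pattern = pd.Series(map(tuple, merged.to_numpy()), index=merged.index)
        dup = pattern.duplicated(keep="first") & merged.index.duplicated(keep="first")
    n_dup_removed = int(dup.sum())
    cleaned = merged.loc[~dup.to_numpy()]

    report = CleaningReport(
        n_input_rows=n_input_rows,
        n_zero_symptom_rows_removed=n_zero_removed,
        n_duplicate_rows_removed=n_dup_removed,
        n_columns_merged=n_columns_merged,
        n_columns_blacklisted=len(blacklisted),
        n_output_rows=cleaned.shape[0],
        n_output_columns=cleaned.shape[1],
    )
    logger.info("cleaning report: %s", report.as_dict())
    return cleaned, report


# -- matrix I/O (delimited text, bit-exact round trip) ----------------------


def write_matrix(
    matrix: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        matrix.rename_axis("patient_id").to_csv(fh, lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col="patient_id", dtype=str)
    return df.astype(np.int8)
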