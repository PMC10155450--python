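"""Turn raw narratives into sets of canonical symptoms.

A narrative mentions a symptom when one of the lexicon's surface forms
occurs as a contiguous token subsequence of the normalised text.  Matching
is greedy: at each position the longest matching surface form wins and the
scan resumes after the matched span (so ``"low mood"`` never additionally
fires a hypothetical ``"mood"`` entry).  Mention multiplicity is discarded —
the downstream encoding is binary.  Negation is ignored by default, matching
the lay usage in the kind of corpora this targets ("I wouldn't be able to
sleep at night" still reports a sleep problem); a simple negation window is
available as an explicit, documented divergence.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .lexicon import SymptomLexicon, normalize

__all__ = [
    "NarrativeRecord",
    "SymptomSet",
    "extract_symptoms",
    "extract_corpus",
    "read_corpus",
    "write_corpus",
]

logger = logging.getLogger(__name__)

#: Tokens treated as negators when the optional negation window is enabled.
NEGATORS = frozenset({"no", "not", "never", "without", "dont", "didnt", "wont", "cant"})


@dataclass(frozen=True)
class NarrativeRecord:
    """One patient's raw narrative."""

    patient_id: str
    text: str


@dataclass(frozen=True)
class SymptomSet:
    """The canonical symptoms extracted from one narrative."""

    patient_id: str
    symptoms: frozenset[str]


def _match_index(lexicon: SymptomLexicon) -> dict[str, list[tuple[tuple[str, ...], str]]]:
    """first token -> [(form tokens, canonical)], longest form first."""
    index: dict[str, list[tuple[tuple[str, ...], str]]] = {}
    for form, canonical in lexicon.form_to_canonical.items():
        tokens = tuple(form.split())
        index.setdefault(tokens[0], []).append((tokens, canonical))
    for forms in index.values():
        forms.sort(key=lambda fc: len(fc[0]), reverse=True)
    return index


def extract_symptoms(
    record: NarrativeRecord,
    lexicon: SymptomLexicon,
    *,
    negation_window: int = 0,
    _index: dict | None = None,
) -> SymptomSet:
    """Extract the canonical symptoms mentioned in one narrative.

    Parameters
    ----------
    negation_window
        If positive, a surface-form match starting within this many tokens
        after a negator token is skipped.  Off (0) by default.
    """
    index = _index if _index is not None else _match_index(lexicon)
    tokens = normalize(record.text)
    found: set[str] = set()
    last_negator = -(10**9)
    i = 0
    while i < len(tokens):
        if negation_window and tokens[i] in NEGATORS:
            last_negator = i
        candidates = index.get(tokens[i], ())
        matched = False
        for form_tokens, canonical in candidates:
            j = i + len(form_tokens)
            if tuple(tokens[i:j]) == form_tokens:
                if not (negation_window and 0 < i - last_negator <= negation_window):
                    found.add(canonical)
                i = j
                matched = True
                break
        if not matched:
            i += 1
    return SymptomSet(record.patient_id, frozenset(found))


def extract_corpus(
    records: Sequence[NarrativeRecord],
    lexicon: SymptomLexicon,
    *,
    negation_window: int = 0,
) -> list[SymptomSet]:
    """Order-preserving extraction over a whole corpus.

    Raises
    ------
    ValueError
        If two records share a patient id.
    """
    seen: set[str] = set()
    for record in records:
        if record.patient_id in seen:
            raise ValueError(f"duplicate patient_id {record.patient_id!r}")
        seen.add(record.patient_id)
    index = _match_index(lexicon)
    out = [
        extract_symptoms(r, lexicon, negation_window=negation_window, _index=index)
        for r in records
    ]
    n_zero = sum(1 for s in out if not s.symptoms)
    logger.info(
        "extracted %d narratives (%d with zero symptoms)", len(out), n_zero
    )
    return out


# -- corpus I/O (two-column delimited text: patient_id TAB narrative) -------


def write_corpus(
    records: Iterable[NarrativeRecord],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient_id", "narrative"])
        for record in records:
            writer.writerow([record.patient_id, record.text])


def read_corpus(path: str | Path) -> list[NarrativeRecord]:
    records: list[NarrativeRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        rows = csv.reader(
            (line for line in fh if not line.startswith("#")),
            delimiter="\t",
        )
        header = next(rows, None)
        if header is None:
            return records
        for row in rows:
            if not row:
                continue
            if len(row) != 2:
                raise ValueError(f"expected two columns, got {row!r}")
            records.append(NarrativeRecord(row[0], row[1]))
    return records
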