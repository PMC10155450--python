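"""Symptom vocabulary: surface forms, canonical names, and text normalisation.

A :class:`SymptomLexicon` is the contract that drives both narrative
extraction and column merging: it maps every *surface form* (a lowercase
token sequence such as ``"hearing voices"`` or ``"panic attacks"``) to a
single *canonical* symptom name, and carries a blacklist of words declared
to be non-symptoms.

Lexicon file format (stanza form), one canonical per stanza::

    lexicon    ::= stanza* blacklist?
    stanza     ::= "canonical:" NAME NEWLINE variant*
    variant    ::= WS "variant:" FORM NEWLINE
    blacklist  ::= "[blacklist]" NEWLINE (WORD NEWLINE)*

Lines starting with ``#`` and blank lines are ignored.  A canonical with no
explicit ``variant:`` lines gets itself as its only surface form.  A
two-column delimited table (``surface_form<TAB or ,>canonical``) is accepted
as an equivalent input format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "LexiconError",
    "SymptomLexicon",
    "normalize",
    "load_lexicon",
    "loads_lexicon",
    "write_lexicon",
    "demo_lexicon",
]


class LexiconError(ValueError):
    """Raised when a lexicon file fails to parse or violates an invariant."""


# Curly apostrophes/quotes from web-scraped text are treated like straight ones.
_APOSTROPHES = str.maketrans({"’": "'", "‘": "'", "ʼ": "'"})
_NON_WORD = re.compile(r"[^a-z0-9'\s]+")


def normalize(text: str) -> list[str]:
    """Normalise raw narrative text into lowercase, punctuation-free tokens.

    Contractions lose their apostrophe (``"don't"`` -> ``"dont"``) so that
    straight and curly apostrophes behave identically.  Idempotent: joining
    the tokens with spaces and normalising again returns the same tokens.
    """
    lowered = text.lower().translate(_APOSTROPHES)
    lowered = _NON_WORD.sub(" ", lowered).replace("'", "")
    return lowered.split()


def _norm_form(form: str) -> str:
    return " ".join(normalize(form))


@dataclass(frozen=True)
class SymptomLexicon:
    """Canonical symptom names, their surface forms, and a non-symptom blacklist.

    Parameters
    ----------
    entries
        Mapping canonical name -> ordered tuple of surface forms.  Both sides
        are stored normalised (lowercase, space-joined tokens).
    blacklist
        Words declared non-symptoms; disjoint from every surface form.
    """

    entries: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    blacklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        norm_entries: dict[str, tuple[str, ...]] = {}
        for canonical, forms in self.entries.items():
            key = _norm_form(canonical)
            if not key:
                raise LexiconError("empty canonical name")
            forms = tuple(dict.fromkeys(_norm_form(f) for f in forms if _norm_form(f)))
            if not forms:
                forms = (key,)  # a bare canonical is its own surface form
            if key in norm_entries:
                raise LexiconError(f"duplicate canonical {key!r}")
            norm_entries[key] = forms
        object.__setattr__(self, "entries", norm_entries)
        object.__setattr__(
            self, "blacklist", frozenset(_norm_form(w) for w in self.blacklist)
        )
        self._validate()

    def _validate(self) -> None:
        seen: dict[str, str] = {}
        for canonical, forms in self.entries.items():
            for form in forms:
                if form in seen and seen[form] != canonical:
                    raise LexiconError(
                        f"surface form {form!r} maps to both {seen[form]!r} "
                        f"and {canonical!r}"
                    )
                seen[form] = canonical
        overlap = self.blacklist & set(seen)
        if overlap:
            raise LexiconError(
                f"blacklist overlaps surface forms: {sorted(overlap)}"
            )

    # -- views -------------------------------------------------------------

    @property
    def canonicals(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @cached_property
    def form_to_canonical(self) -> dict[str, str]:
        """Every surface form -> its canonical name (injective by invariant)."""
        return {f: c for c, forms in self.entries.items() for f in forms}

    @cached_property
    def surface_tokens(self) -> frozenset[str]:
        """Union of all tokens appearing in any surface form."""
        return frozenset(t for f in self.form_to_canonical for t in f.split())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, canonical: str) -> bool:
        return _norm_form(canonical) in self.entries


# -- file I/O ---------------------------------------------------------------


def loads_lexicon(text: str) -> SymptomLexicon:
    """Parse lexicon text in either the stanza or the two-column format."""
    lines = text.splitlines()
    if any(line.strip().startswith("canonical:") for line in lines) or any(
        line.strip() == "[blacklist]" for line in lines
    ):
        return _parse_stanzas(lines)
    return _parse_table(lines)


def _parse_stanzas(lines: list[str]) -> SymptomLexicon:
    entries: dict[str, list[str]] = {}
    blacklist: set[str] = set()
    current: str | None = None
    in_blacklist = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "[blacklist]":
            in_blacklist = True
            current = None
            continue
        if in_blacklist:
            blacklist.add(line)
            continue
        if line.startswith("canonical:"):
            current = line.removeprefix("canonical:").strip()
            if not current:
                raise LexiconError(f"line {lineno}: empty canonical name")
            if _norm_form(current) in entries:
                raise LexiconError(f"line {lineno}: duplicate canonical {current!r}")
            entries[_norm_form(current)] = []
        elif line.startswith("variant:"):
            if current is None:
                raise LexiconError(f"line {lineno}: variant before any canonical")
            entries[_norm_form(current)].append(line.removeprefix("variant:").strip())
        else:
            raise LexiconError(f"line {lineno}: unrecognised line {line!r}")
    return SymptomLexicon(
        {c: tuple(v) for c, v in entries.items()}, frozenset(blacklist)
    )


def _parse_table(lines: list[str]) -> SymptomLexicon:
    entries: dict[str, list[str]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) != 2:
            raise LexiconError(
                f"line {lineno}: expected two columns (surface_form, canonical), "
                f"got {line!r}"
            )
        form, canonical = (p.strip() for p in parts)
        entries.setdefault(_norm_form(canonical), []).append(form)
    return SymptomLexicon({c: tuple(v) for c, v in entries.items()})


def load_lexicon(path: str | Path) -> SymptomLexicon:
    """Read a lexicon file; see the module docstring for the accepted formats."""
    return loads_lexicon(Path(path).read_text(encoding="utf-8"))


def write_lexicon(lexicon: SymptomLexicon, path: str | Path) -> None:
    """Write a lexicon in stanza form; round-trips through :func:`load_lexicon`."""
    out: list[str] = []
    for canonical, forms in lexicon.entries.items():
        out.append(f"canonical: {canonical}")
        out.extend(f"  variant: {form}" for form in forms)
    if lexicon.blacklist:
        out.append("[blacklist]")
        out.extend(sorted(lexicon.blacklist))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def demo_lexicon() -> SymptomLexicon:
    """The small demonstration lexicon shipped with the package (~28 canonicals)."""
    text = (
        resources.files("symptomics.data").joinpath("demo_lexicon.txt").read_text("utf-8")
    )
    return loads_lexicon(text)
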