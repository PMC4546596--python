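"""Categorized medical term lexica.

The framework recognizes six kinds of clinical terms — diseases, symptoms,
drugs, body parts, procedures and clinical tests — by exact surface-string
lookup against per-category dictionaries. Every term carries a provenance
tag recording how it entered the lexicon: shipped with the core dictionaries,
accrued by pattern-iteration bootstrapping, assembled from a body-part
prefix enumeration, or expanded with a directional/extensional prefix.

Terms are stored as raw Unicode strings; the only normalization applied is
whitespace stripping on load. Matching is exact and case-sensitive, because
the downstream tagger matches literal surface forms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Category",
    "Provenance",
    "LexiconSet",
    "load_lexica",
    "save_lexica",
]


class Category(str, enum.Enum):
    """The six term categories of the cross-domain medical dictionary."""

    DISEASE = "disease"
    SYMPTOM = "symptom"
    DRUG = "drug"
    BODY_PART = "body_part"
    PROCEDURE = "procedure"
    CLINICAL_TEST = "clinical_test"


class Provenance(str, enum.Enum):
    """How a term entered the lexicon."""

    CORE = "core"
    PATTERN_ITERATION = "pattern_iteration"
    BODY_PART_ASSEMBLY = "body_part_assembly"
    PREFIX_UPDATE = "prefix_update"


@dataclass
class LexiconSet:
    """Six categorized term dictionaries with per-term provenance.

    A term may belong to several categories simultaneously (a body part
    that is also the prefix of a disease, for instance); each
    ``(term, category)`` pair has exactly one provenance tag, and the first
    origin recorded for a pair wins.
    """

    entries: dict[Category, set[str]] = field(
        default_factory=lambda: {c: set() for c in Category}
    )
    provenance: dict[tuple[str, Category], Provenance] = field(default_factory=dict)

    def add_term(
        self, term: str, category: Category, origin: Provenance = Provenance.CORE
    ) -> None:
        """Add ``term`` to ``category``; first origin wins on re-add."""
        if not term:
            raise ValueError("cannot add an empty term to a lexicon")
        if "\n" in term:
            raise ValueError("terms may not contain newline characters")
        if term not in self.entries[category]:
            self.entries[category].add(term)
            self.provenance[(term, category)] = origin
        # (term, category) already present: keep the original provenance

    def contains(self, term: str, category: Category) -> bool:
        return term in self.entries[category]

    def lookup(self, s: str) -> set[Category]:
        """Every category whose dictionary contains ``s`` exactly."""
        return {c for c, terms in self.entries.items() if s in terms}

    def terms(self, category: Category) -> frozenset[str]:
        return frozenset(self.entries[category])

    def size(self, category: Category | None = None) -> int:
        if category is not None:
            return len(self.entries[category])
        return sum(len(t) for t in self.entries.values())

    def max_term_length(self, categories: Iterable[Category] | None = None) -> int:
        cats = list(categories) if categories is not None else list(Category)
        lengths = [len(t) for c in cats for t in self.entries[c]]
        return max(lengths, default=0)

    def copy(self) -> "LexiconSet":
        return LexiconSet(
            entries={c: set(t) for c, t in self.entries.items()},
            provenance=dict(self.provenance),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LexiconSet):
            return NotImplemented
        return self.entries == other.entries


def load_lexica(paths: Mapping[Category, str | Path]) -> LexiconSet:
    """Load core lexica from term-per-line UTF-8 files.

    Blank lines are skipped, duplicate lines collapse, surrounding
    whitespace is stripped. All loaded terms get ``core`` provenance.
    """
    lex = LexiconSet()
    for category, path in paths.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(
                f"lexicon file for category {category.value!r} not found: {path}"
            )
        raw = path.read_bytes()
        try:
            text = raw.decode("utf-8")
        except UnicodeDecodeError as exc:
            line_no = raw[: exc.start].count(b"\n") + 1
            raise ValueError(
                f"{path} is not valid UTF-8 (category {category.value!r}, "
                f"line {line_no})"
            ) from exc
        for line in text.splitlines():
            term = line.strip()
            if term:
                lex.add_term(term, category, Provenance.CORE)
    return lex


def save_lexica(lex: LexiconSet, directory: str | Path) -> None:
    """Persist one ``<category>.txt`` per category plus a provenance TSV.

    Round-trips through :func:`load_lexica` to an equal ``LexiconSet``
    (set equality per category; provenance is carried in the sibling TSV).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for category in Category:
        terms = sorted(lex.entries[category])
        (directory / f"{category.value}.txt").write_text(
            "".join(t + "\n" for t in terms), encoding="utf-8"
        )
    rows = [
        f"{term}\t{cat.value}\t{lex.provenance[(term, cat)].value}\n"
        for cat in Category
        for term in sorted(lex.entries[cat])
    ]
    (directory / "provenance.tsv").write_text("".join(rows), encoding="utf-8")


def lexica_paths(directory: str | Path) -> dict[Category, Path]:
    """Category → ``<category>.txt`` map for a lexica directory."""
    directory = Path(directory)
    return {c: directory / f"{c.value}.txt" for c in Category}
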