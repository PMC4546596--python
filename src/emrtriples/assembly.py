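"""Compound-term assembly: body-part prefixes and directional prefixes.

Chinese clinical prose abbreviates compound findings as enumerations that
share a body-part prefix or a finding suffix: B1、B2、D ("oral, mucosa
bleeding") reads as B1D and B2D, while B、D1、D2 ("abdominal pain,
vomiting") reads as BD1, D2 — NOT BD2. Which expansions are licensed is
decided from the corpus itself: a non-adjacent pair (B, D) is accepted only
when the probability of B being immediately followed by D in the training
text exceeds a threshold. The probability is conditioned on B's total
occurrence count, ``P(D follows | B) = adjacent(B, D) / count(B)``.

Separately, known terms preceded by directional or extensional modifiers
(左侧 "left", 双 "bilateral", ...) are extended to a new term of the same
category via a three-character look-back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lexicon import Category, LexiconSet
from .tagger import TaggedSpan

__all__ = [
    "AdjacencyTable",
    "PrefixConfig",
    "build_adjacency_table",
    "assemble_enumeration",
    "expand_directional_prefix",
    "ENUM_PUNCT",
    "D_CATEGORIES",
]

#: enumeration separators between the members of a shared-prefix listing
ENUM_PUNCT = "、，"

#: suffix categories D; drug is excluded (compound drug names do not take
#: body-part prefixes)
D_CATEGORIES = frozenset(
    {Category.DISEASE, Category.SYMPTOM, Category.PROCEDURE, Category.CLINICAL_TEST}
)

#: directional/extensional modifiers, single characters and their
#: two-character combinations as seen in clinical text
DEFAULT_DIRECTIONAL = (
    "左", "右", "双", "侧", "上", "下",
    "左侧", "右侧", "双侧", "左上", "左下", "右上", "右下",
)


@dataclass
class AdjacencyTable:
    """Corpus statistics of body-part term B immediately followed by D."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    occurrences: dict[str, int] = field(default_factory=dict)
    threshold: float = 0.01

    def prob(self, b: str, d: str) -> float:
        occ = self.occurrences.get(b, 0)
        if occ == 0:
            return 0.0
        return self.counts.get((b, d), 0) / occ


@dataclass(frozen=True)
class PrefixConfig:
    directional: tuple[str, ...] = DEFAULT_DIRECTIONAL
    lookback: int = 3

    def __post_init__(self) -> None:
        if any(not (1 <= len(p) <= 3) for p in self.directional):
            raise ValueError("directional prefixes must be 1-3 characters long")


def _find_all(doc: str, needle: str) -> list[int]:
    out, i = [], doc.find(needle)
    while i >= 0:
        out.append(i)
        i = doc.find(needle, i + 1)
    return out


def build_adjacency_table(
    corpus: list[str], lex: LexiconSet, threshold: float = 0.01
) -> AdjacencyTable:
    """Count, over the corpus, each body-part term immediately followed by a
    D-category term, and each body-part term's total occurrences."""
    b_terms = sorted(lex.entries[Category.BODY_PART])
    if not b_terms:
        raise ValueError("body_part lexicon is empty")
    d_terms = sorted({t for c in D_CATEGORIES for t in lex.entries[c]})
    table = AdjacencyTable(threshold=threshold)
    for doc in corpus:
        for b in b_terms:
            positions = _find_all(doc, b)
            if not positions:
                continue
            table.occurrences[b] = table.occurrences.get(b, 0) + len(positions)
            for pos in positions:
                tail = pos + len(b)
                for d in d_terms:
                    if doc.startswith(d, tail):
                        key = (b, d)
                        table.counts[key] = table.counts.get(key, 0) + 1
    return table


def assemble_enumeration(
    statement: str,
    spans: list[TaggedSpan],
    table: AdjacencyTable,
    lex: LexiconSet | None = None,
) -> list[TaggedSpan]:
    """Expand a shared-prefix enumeration into compound terms.

    ``spans`` must be enumeration-adjacent in statement order (separated
    only by enumeration punctuation). Two shapes are handled:

    * B1, ..., Bn, D  →  BiD for every i with ``prob(Bi, D) > threshold``;
      the textually adjacent pair Bn+D is always emitted;
    * B, D1, ..., Dn  →  BDj for every j with ``prob(B, Dj) > threshold``;
      the textually adjacent pair B+D1 is always emitted.

    Adjacent-pair compounds are suppressed when the concatenation is
    already a lexicon term (the tagger will have found them whole). Each
    compound takes the D term's category; its span covers the compound's
    components in the statement, and its surface is the concatenation
    B + D (contiguous in the text only for the adjacent pair).
    """
    if len(spans) < 2:
        return []
    spans = sorted(spans, key=lambda s: s.start)
    if not _enumeration_adjacent(statement, spans):
        return []
    cats = [s.category for s in spans]
    out: list[TaggedSpan] = []
    if all(c is Category.BODY_PART for c in cats[:-1]) and cats[-1] in D_CATEGORIES:
        d = spans[-1]
        for i, b in enumerate(spans[:-1]):
            adjacent_pair = i == len(spans) - 2
            out.extend(_compound(b, d, b, d, table, lex, adjacent_pair))
    elif cats[0] is Category.BODY_PART and all(c in D_CATEGORIES for c in cats[1:]):
        b = spans[0]
        for j, d in enumerate(spans[1:]):
            out.extend(_compound(b, d, b, d, table, lex, j == 0))
    return out


def _compound(
    b: TaggedSpan,
    d: TaggedSpan,
    left: TaggedSpan,
    right: TaggedSpan,
    table: AdjacencyTable,
    lex: LexiconSet | None,
    adjacent_pair: bool,
) -> list[TaggedSpan]:
    surface = b.surface + d.surface
    if adjacent_pair:
        if lex is not None and lex.lookup(surface):
            return []
    elif table.prob(b.surface, d.surface) <= table.threshold:
        return []
    return [
        TaggedSpan(
            surface,
            d.category,
            min(left.start, right.start),
            max(left.end, right.end),
        )
    ]


def _enumeration_adjacent(statement: str, spans: list[TaggedSpan]) -> bool:
    for a, b in zip(spans, spans[1:]):
        gap = statement[a.end : b.start]
        if any(ch not in ENUM_PUNCT for ch in gap):
            return False
    return True


def expand_directional_prefix(
    doc: str,
    span: TaggedSpan,
    cfg: PrefixConfig = PrefixConfig(),
    _expanded: set[int] | None = None,
) -> TaggedSpan:
    """Extend a span leftward over directional/extensional modifiers.

    Looks back up to ``cfg.lookback`` characters before the span and takes
    the longest window suffix expressible as a concatenation of configured
    modifier strings. Expansion is performed once; re-expanding an already
    expanded span returns it unchanged (callers track identity via the
    optional ``_expanded`` start-offset set).
    """
    if _expanded is not None and span.start in _expanded:
        return span
    window = doc[max(0, span.start - cfg.lookback) : span.start]
    take = _longest_modifier_suffix(window, cfg.directional)
    if take == 0:
        return span
    start = span.start - take
    out = TaggedSpan(doc[start : span.end], span.category, start, span.end, span.is_event)
    if _expanded is not None:
        _expanded.add(start)
    return out


def _longest_modifier_suffix(window: str, modifiers: tuple[str, ...]) -> int:
    """Length of the longest suffix of ``window`` that is a concatenation
    of modifier strings (dynamic program over suffix lengths)."""
    n = len(window)
    ok = [False] * (n + 1)
    ok[0] = True  # empty suffix
    best = 0
    for take in range(1, n + 1):  # take characters from the right
        for m in modifiers:
            lm = len(m)
            if lm <= take and ok[take - lm] and window[n - take : n - take + lm] == m:
                ok[take] = True
                best = take
                break
    return best
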