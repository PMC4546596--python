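"""Dictionary-driven term tagging and medical-event filtering.

Recognition is recursive longest match: candidate substring lengths are
tried from the longest down to single characters, each starting position
left to right, and a substring is tagged only if neither its first nor its
last character already belongs to a tagged span. This boundary-character
check is what the published algorithm prescribes; it is cheaper than a full
overlap check and, because longer candidates are always tried first, it
still guarantees that emitted spans never overlap.

A clinical narrative describes a single patient, so a recognized term is
assumed to denote an event the patient experienced — except symptoms,
procedures and clinical tests that are negated ("no chills") or scheduled
for the future ("plans to undergo ..."). Those mentions are kept as spans
but flagged ``is_event=False``. Body-part mentions are never events by
themselves; they only feed compound-term assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .lexicon import Category, LexiconSet

__all__ = ["TaggedSpan", "FilterConfig", "tag_terms", "filter_events"]

#: clause punctuation delimiting negation/future scope
CLAUSE_PUNCT = "，、。；："

#: negation prefixes: no / refuse to / deny / haven't seen
DEFAULT_NEGATION_PREFIXES = frozenset({"无", "拒绝", "否认", "未见"})
#: future-action markers: scheduled to / suggest to
DEFAULT_FUTURE_MARKERS = frozenset({"拟", "建议"})
#: only these categories can be demoted to non-events
DEFAULT_FILTERED_CATEGORIES = frozenset(
    {Category.SYMPTOM, Category.PROCEDURE, Category.CLINICAL_TEST}
)


@dataclass(frozen=True)
class TaggedSpan:
    """A recognized term occurrence: ``doc[start:end] == surface``."""

    surface: str
    category: Category
    start: int
    end: int
    is_event: bool = True

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class FilterConfig:
    """Markers and categories for the negation/future event filter."""

    negation_prefixes: frozenset[str] = DEFAULT_NEGATION_PREFIXES
    future_markers: frozenset[str] = DEFAULT_FUTURE_MARKERS
    filtered_categories: frozenset[Category] = DEFAULT_FILTERED_CATEGORIES

    def __post_init__(self) -> None:
        if any(not m for m in self.negation_prefixes | self.future_markers):
            raise ValueError("negation/future markers must be non-empty strings")


def tag_terms(
    s: str,
    lex: LexiconSet,
    categories: set[Category] | frozenset[Category] | None = None,
) -> list[TaggedSpan]:
    """Recursive longest-match tagging of ``s`` against the lexica.

    Returns non-overlapping spans sorted by start offset. A substring
    present in several category dictionaries yields one span per category
    at the same offsets.
    """
    cats = list(categories) if categories is not None else list(Category)
    n = len(s)
    if n == 0:
        return []
    dictionaries = [(c, lex.entries[c]) for c in cats]
    max_len = min(n, lex.max_term_length(cats))
    has_tagged = [False] * n
    out: list[TaggedSpan] = []
    for i in range(max_len, 0, -1):  # candidate length, longest first
        for j in range(0, n - i + 1):  # start position, left to right
            if has_tagged[j] or has_tagged[j + i - 1]:
                continue
            s0 = s[j : j + i]
            hit = False
            for category, terms in dictionaries:
                if s0 in terms:
                    out.append(TaggedSpan(s0, category, j, j + i))
                    hit = True
            if hit:
                for t in range(j, j + i):
                    has_tagged[t] = True
    out.sort(key=lambda sp: (sp.start, sp.category.value))
    return out


def _clause_start(doc: str, pos: int) -> int:
    """Start offset of the clause containing ``pos`` (after the nearest
    preceding clause punctuation, or 0)."""
    for k in range(pos - 1, -1, -1):
        if doc[k] in CLAUSE_PUNCT:
            return k + 1
    return 0


def filter_events(
    doc: str, spans: list[TaggedSpan], cfg: FilterConfig = FilterConfig()
) -> list[TaggedSpan]:
    """Set ``is_event`` on every span.

    A symptom/procedure/clinical-test span is demoted when a negation
    prefix or future marker occurs earlier in its enclosing clause.
    Body-part spans are never events; disease and drug spans always are.
    """
    markers = sorted(cfg.negation_prefixes | cfg.future_markers)
    out: list[TaggedSpan] = []
    for span in spans:
        if span.category is Category.BODY_PART:
            out.append(replace(span, is_event=False))
            continue
        if span.category not in cfg.filtered_categories:
            out.append(replace(span, is_event=True))
            continue
        clause_prefix = doc[_clause_start(doc, span.start) : span.start]
        negated = any(m in clause_prefix for m in markers)
        out.append(replace(span, is_event=not negated))
    return out
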