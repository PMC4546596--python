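"""Weakly supervised lexicon enrichment by pattern iteration.

The disease and drug dictionaries are grown directly from the corpus, with
no annotation: each round tags the corpus with the current lexicon, harvests
literal character-context patterns around every tagged occurrence (up to
three characters, punctuation included, on each side), keeps the patterns
that are both selective and precise, and accepts the new terms those
patterns extract when enough independent patterns agree.

Scores (all computed over *unique* extracted filler strings):

* Pattern Selectivity ``PS`` — number of unique already-known terms a
  pattern extracts from the corpus.
* Pattern Precision ``PP`` — fraction of a pattern's unique fillers that
  are already known, ``PS / (unique fillers)``; undefined when the pattern
  extracts nothing.
* Term Frequency ``TF`` — number of *accepted* patterns that extract a
  candidate term this round; a term seen by more than one pattern is
  trustworthy.

"Already known" at round *k* means: in the core lexicon or accepted in any
round before *k*. A pattern passes when ``PS > PST`` and ``PP > PPT``
(strict); a term is accepted when ``TF > TFT`` (strict). The loop stops
when a round accepts nothing, or after ``max_iterations``.

Context windows count CHARACTERS, not segmenter tokens: general-purpose
Chinese word segmenters break down on clinical prose, and the character
windows are exactly what the worked examples use.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

from .lexicon import Category, LexiconSet, Provenance
from .tagger import TaggedSpan, tag_terms

logger = logging.getLogger(__name__)

__all__ = [
    "CandidatePattern",
    "CandidateTerm",
    "BootstrapConfig",
    "generate_candidate_patterns",
    "apply_pattern",
    "score_patterns",
    "select_patterns",
    "select_terms",
    "bootstrap",
    "grid_search_thresholds",
]

#: statement/clause punctuation a slot filler may not contain
FILLER_PUNCT = "。，、；：!！?？"

#: tuned operating points: disease PST=7/PPT=0.7, drug PST=6/PPT=0.85
TUNED_THRESHOLDS: dict[Category, tuple[int, float]] = {
    Category.DISEASE: (7, 0.7),
    Category.DRUG: (6, 0.85),
}


@dataclass(frozen=True)
class CandidatePattern:
    """A literal left/right character context around a category slot."""

    left: str
    slot_category: Category
    right: str
    ps: int = 0
    pp: float | None = None  # None = undefined (pattern extracted nothing)

    def __str__(self) -> str:  # e.g. 予<DRUG>抗
        return f"{self.left}<{self.slot_category.name}>{self.right}"


@dataclass(frozen=True)
class CandidateTerm:
    surface: str
    tf: int
    category: Category


@dataclass(frozen=True)
class BootstrapConfig:
    """Thresholds and bounds for one bootstrapping run."""

    pst: int = 6
    ppt: float = 0.85
    tft: int = 1
    max_term_len: int = 10
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if self.pst < 1 or not (0 < self.ppt <= 1) or self.tft < 0:
            raise ValueError("invalid thresholds: need pst>=1, 0<ppt<=1, tft>=0")
        if self.max_term_len < 1:
            raise ValueError("max_term_len must be >= 1")


@dataclass
class IterationRecord:
    """Per-round bookkeeping: the added-terms-per-iteration curve."""

    iteration: int
    n_patterns_kept: int
    n_terms_added: int
    added_terms: list[str] = field(default_factory=list)


def generate_candidate_patterns(doc: str, span: TaggedSpan) -> list[CandidatePattern]:
    """The up-to-nine context patterns around one tagged occurrence.

    One pattern per (left length, right length) with lengths 1..3,
    truncated to the available context at document boundaries and
    deduplicated, so a span flush against a boundary yields fewer than
    nine distinct patterns.
    """
    if not (0 <= span.start <= span.end <= len(doc)) or doc[span.start : span.end] != span.surface:
        raise ValueError(f"span {span!r} out of bounds or inconsistent with document")
    seen: set[tuple[str, str]] = set()
    out: list[CandidatePattern] = []
    for l_len, r_len in itertools.product((1, 2, 3), repeat=2):
        left = doc[max(0, span.start - l_len) : span.start]
        right = doc[span.end : span.end + r_len]
        if (left, right) in seen:
            continue
        seen.add((left, right))
        out.append(CandidatePattern(left, span.category, right))
    return out


def apply_pattern(
    pattern: CandidatePattern,
    corpus: list[str],
    cfg: BootstrapConfig = BootstrapConfig(),
) -> set[str]:
    """Slot fillers the pattern extracts from the corpus.

    At every occurrence of the left context the filler is the shortest
    non-empty string reaching the next occurrence of the right context
    (shortest match per anchor). Fillers longer than ``cfg.max_term_len``
    or containing statement/clause punctuation are rejected; any longer
    filler at the same anchor would contain the same defect, so rejection
    per anchor is final.
    """
    fillers: set[str] = set()
    left, right = pattern.left, pattern.right
    for doc in corpus:
        n = len(doc)
        if left:
            anchors = _find_all(doc, left)
            starts = [a + len(left) for a in anchors]
        else:
            starts = range(n)
        for s in starts:
            p = doc.find(right, s + 1) if right else -1
            if p < 0:
                continue
            filler = doc[s:p]
            if 1 <= len(filler) <= cfg.max_term_len and not any(
                ch in FILLER_PUNCT for ch in filler
            ):
                fillers.add(filler)
    return fillers


def _find_all(doc: str, needle: str) -> list[int]:
    out, i = [], doc.find(needle)
    while i >= 0:
        out.append(i)
        i = doc.find(needle, i + 1)  # overlapping starts allowed
    return out


def score_patterns(
    patterns: list[CandidatePattern],
    corpus: list[str],
    lex: LexiconSet,
    cfg: BootstrapConfig = BootstrapConfig(),
) -> list[CandidatePattern]:
    """Fill PS and PP for each pattern against the current lexicon."""
    out = []
    for pat in patterns:
        fillers = apply_pattern(pat, corpus, cfg)
        known = lex.entries[pat.slot_category]
        ps = sum(1 for f in fillers if f in known)
        pp = ps / len(fillers) if fillers else None
        out.append(replace(pat, ps=ps, pp=pp))
    return out


def select_patterns(
    patterns: list[CandidatePattern], cfg: BootstrapConfig
) -> list[CandidatePattern]:
    """Keep exactly the patterns with ``PS > PST`` and ``PP > PPT``."""
    return [
        p
        for p in patterns
        if p.pp is not None and p.ps > cfg.pst and p.pp > cfg.ppt
    ]


def select_terms(
    candidates: list[CandidateTerm], cfg: BootstrapConfig
) -> list[CandidateTerm]:
    """Keep exactly the candidates with ``TF > TFT``."""
    return [t for t in candidates if t.tf > cfg.tft]


def bootstrap(
    corpus: list[str],
    lex: LexiconSet,
    category: Category,
    cfg: BootstrapConfig | None = None,
) -> tuple[LexiconSet, list[IterationRecord]]:
    """Iteratively enrich one category's lexicon from the corpus.

    Returns an enriched copy of ``lex`` (accepted terms carry
    ``pattern_iteration`` provenance) and the per-round history. The input
    lexicon is not mutated.
    """
    if cfg is None:
        pst, ppt = TUNED_THRESHOLDS.get(category, (6, 0.85))
        cfg = BootstrapConfig(pst=pst, ppt=ppt)
    lex = lex.copy()
    history: list[IterationRecord] = []
    for it in range(1, cfg.max_iterations + 1):
        # harvest context patterns around every tagged occurrence
        seen: set[tuple[str, str]] = set()
        patterns: list[CandidatePattern] = []
        for doc in corpus:
            for span in tag_terms(doc, lex, {category}):
                for pat in generate_candidate_patterns(doc, span):
                    key = (pat.left, pat.right)
                    if key not in seen:
                        seen.add(key)
                        patterns.append(pat)
        scored = score_patterns(patterns, corpus, lex, cfg)
        accepted = select_patterns(scored, cfg)
        # TF = number of accepted patterns extracting each new filler
        tf: dict[str, int] = {}
        for pat in accepted:
            for f in apply_pattern(pat, corpus, cfg):
                if f not in lex.entries[category]:
                    tf[f] = tf.get(f, 0) + 1
        candidates = [CandidateTerm(s, n, category) for s, n in sorted(tf.items())]
        added = [t.surface for t in select_terms(candidates, cfg)]
        for term in added:
            lex.add_term(term, category, Provenance.PATTERN_ITERATION)
        history.append(IterationRecord(it, len(accepted), len(added), added))
        logger.info(
            "bootstrap %s round %d: %d patterns kept, %d terms added",
            category.value, it, len(accepted), len(added),
        )
        if not added:
            break
    return lex, history


def grid_search_thresholds(
    corpus: list[str],
    lex: LexiconSet,
    category: Category,
    gold_spans: list[list[TaggedSpan]],
    tuning_docs: list[str],
    pst_grid: list[int] | None = None,
    ppt_grid: list[float] | None = None,
    cfg: BootstrapConfig | None = None,
) -> tuple[int, float, list[tuple[int, float, float]]]:
    """Grid-search PST/PPT maximizing exact-match tagging F1 on a tuning set.

    Default grids: PST 3..10 step 1, PPT 0.30..0.90 step 0.05. Ties break
    toward higher PPT, then higher PST (the more conservative setting).
    Returns (best_pst, best_ppt, [(pst, ppt, f1), ...]).
    """
    if not gold_spans or not any(gold_spans):
        raise ValueError("grid search needs non-empty gold annotations")
    if pst_grid is None:
        pst_grid = list(range(3, 11))
    if ppt_grid is None:
        ppt_grid = [round(0.30 + 0.05 * k, 2) for k in range(13)]
    base = cfg or BootstrapConfig()
    table: list[tuple[int, float, float]] = []
    best: tuple[float, float, int] | None = None  # (f1, ppt, pst)
    for pst in pst_grid:
        for ppt in ppt_grid:
            run_cfg = replace(base, pst=pst, ppt=ppt)
            enriched, _ = bootstrap(corpus, lex, category, run_cfg)
            f1 = _tagging_f1(tuning_docs, gold_spans, enriched, category)
            table.append((pst, ppt, f1))
            key = (f1, ppt, pst)
            if best is None or key > best:
                best = key
    assert best is not None
    return best[2], best[1], table


def _tagging_f1(
    docs: list[str],
    gold_spans: list[list[TaggedSpan]],
    lex: LexiconSet,
    category: Category,
) -> float:
    tp = fp = fn = 0
    for doc, gold in zip(docs, gold_spans):
        pred = {
            (sp.start, sp.end)
            for sp in tag_terms(doc, lex, {category})
        }
        ref = {(sp.start, sp.end) for sp in gold if sp.category is category}
        tp += len(pred & ref)
        fp += len(pred - ref)
        fn += len(ref - pred)
    if tp == 0:
        return 0.0
    p, r = tp / (tp + fp), tp / (tp + fn)
    return 2 * p * r / (p + r)
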