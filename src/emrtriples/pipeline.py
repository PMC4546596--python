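"""End-to-end extraction and evaluation.

``extract_document`` runs the full chain on one narrative: statement
splitting, longest-match tagging, compound-term assembly, directional
prefix expansion, negation/future event filtering, temporal extraction and
scoping, candidate-description extraction and filtering, and pair
classification — emitting (time, event, description) triples in document
order.

``evaluate`` scores predictions against gold at three levels (span,
time-link, triple), each in exact mode (identical offsets) or inexact mode
(any character overlap with a gold entity of the same category).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .assembly import (
    ENUM_PUNCT,
    AdjacencyTable,
    PrefixConfig,
    assemble_enumeration,
    expand_directional_prefix,
)
from .lexicon import LexiconSet
from .linker import (
    CandidateDescription,
    DEFAULT_STOPLIST,
    LinkerModel,
    Triple,
    baseline_adjacent,
    extract_candidates,
    filter_candidates,
    link,
)
from .tagger import FilterConfig, TaggedSpan, filter_events, tag_terms
from .temporal import (
    TemporalTerm,
    TemporalVocab,
    assign_time_scopes,
    extract_temporal_terms,
    split_statements,
)

logger = logging.getLogger(__name__)

__all__ = ["Resources", "EvalResult", "extract_document", "evaluate"]


@dataclass
class Resources:
    """Everything a single extraction run needs."""

    lexica: LexiconSet
    adjacency: AdjacencyTable | None = None
    prefix_config: PrefixConfig | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    temporal_vocab: TemporalVocab | None = None
    linker_model: LinkerModel | None = None
    frequency_provider: object | None = None
    stoplist: frozenset[str] = DEFAULT_STOPLIST
    use_adjacent_baseline: bool = False  # link by adjacency when no model


@dataclass(frozen=True)
class EvalResult:
    recall: float
    precision: float
    f1: float
    mode: str  # exact | inexact
    level: str  # span | time_link | triple


def _shift_span(sp: TaggedSpan, off: int) -> TaggedSpan:
    return replace(sp, start=sp.start + off, end=sp.end + off)


def _shift_time(t: TemporalTerm, off: int) -> TemporalTerm:
    return TemporalTerm(t.surface, t.start + off, t.end + off, t.kind)


def _shift_cand(c: CandidateDescription, off: int) -> CandidateDescription:
    return CandidateDescription(c.surface, c.start + off, c.end + off, c.contains_digit)


def extract_document(doc: str, resources: Resources) -> list[Triple]:
    """Extract all (time, event, description) triples from one narrative.

    Offsets in the returned triples are document-level. Events with no
    accepted description yield a triple with ``description=None``; an
    event with several accepted descriptions yields one triple per link.
    """
    res = resources
    statements = split_statements(doc)
    scope_input = []
    per_statement = []
    expanded_starts: set[int] = set()
    for off, stmt in statements:
        spans = tag_terms(stmt, res.lexica)
        if res.adjacency is not None and len(spans) >= 2:
            spans = spans + _assembled_compounds(stmt, spans, res.adjacency, res.lexica)
        if res.prefix_config is not None:
            spans = [
                expand_directional_prefix(stmt, sp, res.prefix_config, expanded_starts)
                for sp in spans
            ]
        spans = filter_events(stmt, spans, res.filter_config)
        times = extract_temporal_terms(stmt, res.temporal_vocab)
        events = [sp for sp in spans if sp.is_event]
        cands = filter_candidates(
            extract_candidates(stmt, spans, times), spans, res.stoplist
        )
        if res.linker_model is not None and events and cands:
            links = link(
                res.linker_model, stmt, events, cands, spans, res.frequency_provider
            )
        elif res.use_adjacent_baseline:
            links = baseline_adjacent(events, cands)
        else:
            links = []
        times_g = [_shift_time(t, off) for t in times]
        events_g = [_shift_span(e, off) for e in events]
        links_g = [
            (_shift_span(e, off), _shift_cand(c, off)) for e, c in links
        ]
        scope_input.append((stmt, times_g, events_g))
        per_statement.append((events_g, links_g))
        logger.info(
            "statement @%d: %d spans, %d times, %d candidates, %d links",
            off, len(spans), len(times), len(cands), len(links),
        )
    assigned = dict(
        ((ev.start, ev.end, ev.category), t)
        for ev, t in assign_time_scopes(scope_input)
    )
    triples: list[Triple] = []
    for events_g, links_g in per_statement:
        for ev in events_g:
            t = assigned.get((ev.start, ev.end, ev.category))
            descs = [c for e, c in links_g if e == ev]
            if descs:
                triples.extend(Triple(t, ev, c) for c in descs)
            else:
                triples.append(Triple(t, ev, None))
    return triples


def _assembled_compounds(
    stmt: str,
    spans: list[TaggedSpan],
    table: AdjacencyTable,
    lex: LexiconSet,
) -> list[TaggedSpan]:
    """Try assembly on every maximal run of enumeration-adjacent spans."""
    spans = sorted(spans, key=lambda s: s.start)
    out: list[TaggedSpan] = []
    run: list[TaggedSpan] = []
    for sp in spans:
        if run and not all(
            ch in ENUM_PUNCT for ch in stmt[run[-1].end : sp.start]
        ):
            out.extend(assemble_enumeration(stmt, run, table, lex))
            run = []
        run.append(sp)
    if run:
        out.extend(assemble_enumeration(stmt, run, table, lex))
    return out


# --------------------------------------------------------------- evaluation


def evaluate(
    pred: Mapping[str, Sequence],
    gold: Mapping[str, Sequence],
    mode: str = "exact",
    level: str = "span",
    desc_overlap: bool = False,
) -> EvalResult:
    """Precision/recall/F1 of predictions against gold.

    ``pred`` and ``gold`` map document ids to per-document items:
    ``TaggedSpan`` lists for the span level, ``Triple`` lists for the
    time_link and triple levels. Exact mode requires identical offsets
    (and, at the triple level, equal time surfaces and description
    intervals); inexact mode relaxes the *event/span* offsets to any
    overlap with a same-category gold entity.
    """
    if mode not in ("exact", "inexact") or level not in ("span", "time_link", "triple"):
        raise ValueError(f"unknown mode/level: {mode}/{level}")
    if set(pred) != set(gold):
        raise ValueError("prediction and gold document ids differ")
    n_pred = n_gold = correct_pred = covered_gold = 0
    for doc_id in sorted(gold):
        p_items, g_items = list(pred[doc_id]), list(gold[doc_id])
        n_pred += len(p_items)
        n_gold += len(g_items)
        correct_pred += sum(
            1
            for p in p_items
            if any(_match(p, g, mode, level, desc_overlap) for g in g_items)
        )
        covered_gold += sum(
            1
            for g in g_items
            if any(_match(p, g, mode, level, desc_overlap) for p in p_items)
        )
    precision = correct_pred / n_pred if n_pred else 0.0
    recall = covered_gold / n_gold if n_gold else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalResult(recall, precision, f1, mode, level)


def _span_match(p: TaggedSpan, g: TaggedSpan, mode: str) -> bool:
    if p.category is not g.category:
        return False
    if mode == "exact":
        return (p.start, p.end) == (g.start, g.end)
    return p.start < g.end and g.start < p.end


def _match(p, g, mode: str, level: str, desc_overlap: bool = False) -> bool:
    if level == "span":
        return _span_match(p, g, mode)
    if not _span_match(p.event, g.event, mode):
        return False
    p_time = p.time.surface if p.time is not None else None
    g_time = g.time.surface if g.time is not None else None
    if p_time != g_time:
        return False
    if level == "time_link":
        return True
    p_desc = (p.description.start, p.description.end) if p.description else None
    g_desc = (g.description.start, g.description.end) if g.description else None
    if desc_overlap and p_desc is not None and g_desc is not None:
        return p_desc[0] < g_desc[1] and g_desc[0] < p_desc[1]
    return p_desc == g_desc
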