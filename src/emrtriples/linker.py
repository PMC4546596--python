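"""Event–description linking with local-context and NGD features.

After tagging and temporal extraction, whatever text remains in a
statement forms candidate descriptions — clauses elaborating an event's
quality, outcome or measurement ("color yellow, sticky" for an
expectoration, "FEV1/FVC less than 70%" for a spirometry). Every
(event, description) pair within a statement is scored by a binary
max-margin classifier over eight features:

local context
    1. up to three characters before/after the event term;
    2. up to three characters before/after the description;
    3. whether the description contains digits;
semantic
    4. Normalized Google Distance between event and description surfaces,
       ``NGD(x, y) = (max(log f(x), log f(y)) - log f(x, y))
       / (log M - min(log f(x), log f(y)))``
       where f are occurrence counts and M the collection size;
    5. number of recognized terms between the pair;
    6. number of candidate descriptions between the pair;
    7. number of commas between the pair;
    8. the event term's category.

Descriptions are sparse and often colloquial, so pure local context
underdetermines the link; NGD contributes a corpus-scale relatedness
signal. The frequency source is pluggable: the shipped default counts
document frequencies in the training corpus (search-engine hit counts,
which the distance was originally defined over, can be supplied through
the same interface from a cached-count file). Linking is many-to-many —
one description may serve several events and vice versa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MaxAbsScaler
from sklearn.svm import SVC

from .lexicon import Category
from .tagger import TaggedSpan
from .temporal import TemporalTerm

__all__ = [
    "CandidateDescription",
    "CorpusFrequencyProvider",
    "CachedFrequencyProvider",
    "PairFeatures",
    "Triple",
    "DEFAULT_STOPLIST",
    "extract_candidates",
    "filter_candidates",
    "ngd",
    "featurize",
    "train_linker",
    "link",
    "baseline_adjacent",
    "LinkerModel",
]

#: clause punctuation splitting a statement into description-bearing clauses
CLAUSE_PUNCT = "，、；："

#: common EMR words whose presence disqualifies a candidate description:
#: hospital admission, discharge, hospitalize, visit a doctor, treatment
DEFAULT_STOPLIST = frozenset({"入院", "出院", "住院", "就诊", "治疗"})

_STRIP_CHARS = "，、；：。！？!?（）()　 \t"
_PAD = "§"  # boundary sentinel for context windows


@dataclass(frozen=True)
class CandidateDescription:
    surface: str
    start: int
    end: int
    contains_digit: bool


@dataclass(frozen=True)
class PairFeatures:
    ctx_term_left: str
    ctx_term_right: str
    ctx_desc_left: str
    ctx_desc_right: str
    has_digit: bool
    ngd: float
    n_terms_between: int
    n_descs_between: int
    n_commas_between: int
    term_type: Category

    def as_dicts(self) -> tuple[dict[str, str], list[float]]:
        cat = {
            "ctx_term_left": self.ctx_term_left,
            "ctx_term_right": self.ctx_term_right,
            "ctx_desc_left": self.ctx_desc_left,
            "ctx_desc_right": self.ctx_desc_right,
            "term_type": self.term_type.value,
        }
        num = [
            float(self.has_digit),
            self.ngd,
            float(self.n_terms_between),
            float(self.n_descs_between),
            float(self.n_commas_between),
        ]
        return cat, num


@dataclass(frozen=True)
class Triple:
    """One structured output record: (time, event, optional description)."""

    time: TemporalTerm | None
    event: TaggedSpan
    description: CandidateDescription | None


class CorpusFrequencyProvider:
    """Document-frequency counts over a fixed document collection.

    ``f(x)`` = number of documents containing ``x`` as a substring,
    ``f2(x, y)`` = number containing both, ``M`` = collection size.
    """

    def __init__(self, documents: Sequence[str]):
        self.documents = list(documents)
        self._doc_cache: dict[str, frozenset[int]] = {}

    @property
    def M(self) -> int:
        return len(self.documents)

    def _docs_with(self, term: str) -> frozenset[int]:
        hit = self._doc_cache.get(term)
        if hit is None:
            hit = frozenset(
                i for i, d in enumerate(self.documents) if term and term in d
            )
            self._doc_cache[term] = hit
        return hit

    def f(self, term: str) -> int:
        return len(self._docs_with(term))

    def f2(self, x: str, y: str) -> int:
        return len(self._docs_with(x) & self._docs_with(y))


class CachedFrequencyProvider:
    """Frequency counts from precomputed tables (e.g. cached search-engine
    hit counts), keyed by term and by unordered term pair."""

    def __init__(
        self,
        f: Mapping[str, int],
        f2: Mapping[tuple[str, str], int],
        M: int,
    ):
        self._f = dict(f)
        self._f2 = {tuple(sorted(k)): v for k, v in f2.items()}
        self.M = M

    def f(self, term: str) -> int:  # type: ignore[no-redef]
        return self._f.get(term, 0)

    def f2(self, x: str, y: str) -> int:
        return self._f2.get(tuple(sorted((x, y))), 0)


def ngd(x: str, y: str, fp, cap: float = 10.0) -> float:
    """Normalized Google Distance between two surface strings.

    0 for terms that always co-occur; grows with dissociation. Undefined
    cases (any zero frequency, or a term occurring in every document) are
    mapped to ``cap`` so feature vectors stay finite; the result is
    clamped to ``[0, cap]``. Symmetric in (x, y); the log base cancels.
    """
    M = fp.M
    if M < 2:
        raise ValueError("frequency provider must index at least 2 documents")
    fx, fy, fxy = fp.f(x), fp.f(y), fp.f2(x, y)
    if fx == 0 or fy == 0 or fxy == 0:
        return cap
    denom = math.log(M) - min(math.log(fx), math.log(fy))
    if denom <= 0:
        return cap
    value = (max(math.log(fx), math.log(fy)) - math.log(fxy)) / denom
    return min(max(value, 0.0), cap)


def extract_candidates(
    statement: str,
    spans: Sequence[TaggedSpan],
    times: Sequence[TemporalTerm],
) -> list[CandidateDescription]:
    """Uncovered clause segments of a statement, as description candidates.

    The statement is split at clause punctuation; within each clause the
    maximal character runs not covered by tagged spans or temporal terms,
    stripped of punctuation and whitespace, become candidates.
    """
    n = len(statement)
    covered = [False] * n
    for sp in spans:
        for k in range(sp.start, sp.end):
            covered[k] = True
    for t in times:
        for k in range(t.start, t.end):
            covered[k] = True
    for k, ch in enumerate(statement):
        if ch in CLAUSE_PUNCT:
            covered[k] = True
    out: list[CandidateDescription] = []
    run_start: int | None = None
    for k in range(n + 1):
        if k < n and not covered[k]:
            if run_start is None:
                run_start = k
            continue
        if run_start is not None:
            out.append(_make_candidate(statement, run_start, k))
            run_start = None
    return [c for c in out if c is not None]


def _make_candidate(
    statement: str, start: int, end: int
) -> CandidateDescription | None:
    while start < end and statement[start] in _STRIP_CHARS:
        start += 1
    while end > start and statement[end - 1] in _STRIP_CHARS:
        end -= 1
    if end <= start:
        return None
    surface = statement[start:end]
    return CandidateDescription(
        surface, start, end, any(ch.isdigit() for ch in surface)
    )


def filter_candidates(
    cands: Sequence[CandidateDescription],
    spans: Sequence[TaggedSpan],
    stoplist: frozenset[str] | set[str] = DEFAULT_STOPLIST,
) -> list[CandidateDescription]:
    """Drop candidates overlapping non-event mentions or containing
    common EMR stopwords."""
    non_event = [sp for sp in spans if not sp.is_event]
    out = []
    for c in cands:
        if any(sp.overlaps(c.start, c.end) for sp in non_event):
            continue
        if any(w in c.surface for w in stoplist):
            continue
        out.append(c)
    return out


def featurize(
    statement: str,
    event: TaggedSpan,
    cand: CandidateDescription,
    spans: Sequence[TaggedSpan],
    cands: Sequence[CandidateDescription],
    fp,
    cap: float = 10.0,
) -> PairFeatures:
    """The eight-feature vector for one (event, candidate) pair.

    Both members must lie within ``statement`` (offsets local to it);
    between-counts use the interval strictly between the pair.
    """
    n = len(statement)
    for start, end, what in (
        (event.start, event.end, "event"),
        (cand.start, cand.end, "candidate"),
    ):
        if not (0 <= start <= end <= n):
            raise ValueError(f"{what} offsets outside the statement: ({start},{end})")
    lo = min(event.end, cand.end)
    hi = max(event.start, cand.start)
    between = statement[lo:hi] if lo < hi else ""
    n_terms = sum(1 for sp in spans if lo <= sp.start and sp.end <= hi)
    n_descs = sum(
        1
        for c in cands
        if lo <= c.start and c.end <= hi and (c.start, c.end) != (cand.start, cand.end)
    )
    n_commas = sum(1 for ch in between if ch in "，、")
    return PairFeatures(
        ctx_term_left=_ctx(statement, event.start, -3),
        ctx_term_right=_ctx(statement, event.end, +3),
        ctx_desc_left=_ctx(statement, cand.start, -3),
        ctx_desc_right=_ctx(statement, cand.end, +3),
        has_digit=cand.contains_digit,
        ngd=ngd(event.surface, cand.surface, fp, cap),
        n_terms_between=n_terms,
        n_descs_between=n_descs,
        n_commas_between=n_commas,
        term_type=event.category,
    )


def _ctx(statement: str, pos: int, width: int) -> str:
    if width < 0:
        chunk = statement[max(0, pos + width) : pos]
        return chunk.rjust(-width, _PAD)
    chunk = statement[pos : pos + width]
    return chunk.ljust(width, _PAD)


@dataclass
class LinkerModel:
    """DictVectorizer one-hot categoricals + scaled numerics + linear SVM."""

    vectorizer: DictVectorizer
    pipeline: Pipeline
    ablate_ngd: bool = False

    def _matrix(self, feats: Sequence[PairFeatures]) -> np.ndarray:
        cat_dicts, num_rows = [], []
        for f in feats:
            cat, num = f.as_dicts()
            if self.ablate_ngd:
                num = num[:1] + num[2:]
            cat_dicts.append(cat)
            num_rows.append(num)
        X_cat = self.vectorizer.transform(cat_dicts)
        return np.hstack([X_cat.toarray(), np.asarray(num_rows)])

    def predict(self, feats: Sequence[PairFeatures]) -> np.ndarray:
        if not feats:
            return np.zeros(0, dtype=bool)
        return self.pipeline.predict(self._matrix(feats)).astype(bool)


def train_linker(
    pairs: Sequence[tuple[PairFeatures, bool]],
    seed: int = 0,
    ablate_ngd: bool = False,
) -> LinkerModel:
    """Fit the binary max-margin pair classifier.

    Categorical features are one-hot encoded over the training vocabulary
    (unseen values at prediction time fall into an all-zeros bucket);
    numeric features are scaled. Linear kernel, balanced class weights,
    deterministic under ``seed``. ``ablate_ngd`` drops feature 4 for
    ablation studies.
    """
    labels = [bool(lab) for _, lab in pairs]
    if len(set(labels)) < 2:
        raise ValueError("training needs at least one example of each class")
    model = LinkerModel(
        vectorizer=DictVectorizer(sparse=True),
        pipeline=Pipeline(
            [
                ("scale", MaxAbsScaler()),
                (
                    "svm",
                    SVC(
                        kernel="linear",
                        C=1.0,
                        class_weight="balanced",
                        random_state=seed,
                    ),
                ),
            ]
        ),
        ablate_ngd=ablate_ngd,
    )
    cat_dicts = []
    num_rows = []
    for f, _ in pairs:
        cat, num = f.as_dicts()
        if ablate_ngd:
            num = num[:1] + num[2:]
        cat_dicts.append(cat)
        num_rows.append(num)
    X_cat = model.vectorizer.fit_transform(cat_dicts)
    X = np.hstack([X_cat.toarray(), np.asarray(num_rows)])
    model.pipeline.fit(X, np.asarray(labels))
    return model


def link(
    model: LinkerModel,
    statement: str,
    events: Sequence[TaggedSpan],
    candidates: Sequence[CandidateDescription],
    spans: Sequence[TaggedSpan],
    fp,
) -> list[tuple[TaggedSpan, CandidateDescription]]:
    """Score every same-statement (event, candidate) pair; keep the pairs
    the classifier accepts. Many-to-many links are allowed."""
    pairs = [(e, c) for e in events for c in candidates]
    if not pairs:
        return []
    feats = [
        featurize(statement, e, c, spans, candidates, fp) for e, c in pairs
    ]
    keep = model.predict(feats)
    return [pair for pair, k in zip(pairs, keep) if k]


def baseline_adjacent(
    events: Sequence[TaggedSpan],
    candidates: Sequence[CandidateDescription],
) -> list[tuple[TaggedSpan, CandidateDescription]]:
    """Each event links to the nearest candidate starting at or after the
    event's end — the simple adjacency baseline."""
    out = []
    for e in events:
        following = [c for c in candidates if c.start >= e.end]
        if following:
            out.append((e, min(following, key=lambda c: c.start)))
    return out
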