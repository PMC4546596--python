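"""Temporal expression extraction and event-time scoping.

Two surface forms of temporal terms are recognized, built from editable
vocabularies, plus six idioms the grammar does not cover:

* relative durations — ``(Pre-AW)? Numbers (Unit)? TemporalUnit (Post-AW)?
  Preposition``, e.g. 约3个月前 (about three months ago);
* day references — ``Day (PeriodOfDay)? ((Pre-AW)? TimeOfDay (Post-AW)?)?``,
  e.g. 昨天下午3点左右 (around 3pm yesterday afternoon);
* idioms — 昨夜, 昨晚, 今夜, 今晚, 今早, 今晨.

Numbers match Arabic digits and Chinese numerals. Extraction is
leftmost-longest and non-overlapping. No normalization to calendar dates is
performed: events are linked to the temporal *surface* term.

Scoping works on statements — the text up to a Chinese period 。:

1. a single time in a statement covers the whole statement;
2. with several times, each covers from its own start to the next time's
   start (the prefix before the first time falls to the carried-forward
   time when one exists, else to the first time);
3. a statement with no time inherits the last time of any earlier
   statement; events before any time in the document get ``UNSPECIFIED``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .tagger import TaggedSpan

__all__ = [
    "TemporalTerm",
    "TemporalVocab",
    "UNSPECIFIED",
    "extract_temporal_terms",
    "assign_time_scopes",
    "split_statements",
]

#: sentinel time assignment for events preceding any temporal term
UNSPECIFIED = None


@dataclass(frozen=True)
class TemporalTerm:
    surface: str
    start: int
    end: int
    kind: str  # relative_duration | day_reference | idiom


@dataclass(frozen=True)
class TemporalVocab:
    """Editable word lists feeding the temporal grammar."""

    pre_aw: tuple[str, ...] = ("约", "大约", "近")
    post_aw: tuple[str, ...] = ("左右", "余", "多")
    units: tuple[str, ...] = ("个", "余", "多")
    temporal_units: tuple[str, ...] = (
        "年", "月", "周", "天", "日", "小时", "分钟", "星期", "礼拜",
    )
    prepositions: tuple[str, ...] = ("前", "后", "来", "内")
    days: tuple[str, ...] = (
        "昨天", "今天", "前天", "昨日", "今日", "前日", "当天", "当日", "次日", "今", "昨",
    )
    periods: tuple[str, ...] = (
        "上午", "下午", "中午", "凌晨", "清晨", "晚上", "夜间", "傍晚", "早上",
    )
    idioms: tuple[str, ...] = ("昨夜", "昨晚", "今夜", "今晚", "今早", "今晨")
    numbers: str = r"(?:[0-9０-９]+|[一二三四五六七八九十两半百千]+)"

    def _alt(self, words: Sequence[str]) -> str:
        # longest alternative first so the regex itself is longest-match
        return "(?:" + "|".join(
            re.escape(w) for w in sorted(words, key=len, reverse=True)
        ) + ")"

    def compile(self) -> list[tuple[str, re.Pattern[str]]]:
        num = self.numbers
        time_of_day = (
            rf"(?:[0-9０-９]{{1,2}}[:：][0-9０-９]{{2}}|{num}点(?:半|{num}分?)?)"
        )
        duration = (
            rf"{self._alt(self.pre_aw)}?"
            rf"{num}"
            rf"{self._alt(self.units)}?"
            rf"{self._alt(self.temporal_units)}"
            rf"{self._alt(self.post_aw)}?"
            rf"{self._alt(self.prepositions)}"
        )
        day_ref = (
            rf"{self._alt(self.days)}"
            rf"{self._alt(self.periods)}?"
            rf"(?:{self._alt(self.pre_aw)}?{time_of_day}{self._alt(self.post_aw)}?)?"
        )
        return [
            ("relative_duration", re.compile(duration)),
            ("day_reference", re.compile(day_ref)),
            ("idiom", re.compile(self._alt(self.idioms))),
        ]


_DEFAULT_VOCAB = TemporalVocab()
_DEFAULT_COMPILED = _DEFAULT_VOCAB.compile()


def extract_temporal_terms(
    statement: str, vocab: TemporalVocab | None = None
) -> list[TemporalTerm]:
    """All non-overlapping, leftmost-longest temporal terms in a statement."""
    compiled = _DEFAULT_COMPILED if vocab is None else vocab.compile()
    out: list[TemporalTerm] = []
    pos, n = 0, len(statement)
    while pos < n:
        best: tuple[int, str] | None = None  # (end, kind)
        for kind, pat in compiled:
            m = pat.match(statement, pos)
            if m and m.end() > m.start():
                if best is None or m.end() > best[0]:
                    best = (m.end(), kind)
        if best is None:
            pos += 1
            continue
        end, kind = best
        out.append(TemporalTerm(statement[pos:end], pos, end, kind))
        pos = end
    return out


def split_statements(doc: str, boundaries: str = "。") -> list[tuple[int, str]]:
    """Split a document into (offset, statement) pairs at period symbols.

    The boundary character is not part of any statement; a trailing
    segment without a final period still counts as a statement.
    """
    out: list[tuple[int, str]] = []
    start = 0
    for i, ch in enumerate(doc):
        if ch in boundaries:
            if i > start:
                out.append((start, doc[start:i]))
            start = i + 1
    if start < len(doc):
        out.append((start, doc[start:]))
    return out


def assign_time_scopes(
    statements: Sequence[tuple[str, Sequence[TemporalTerm], Sequence[TaggedSpan]]],
) -> list[tuple[TaggedSpan, TemporalTerm | None]]:
    """Assign every event span its covering temporal term.

    ``statements`` are in document order; offsets of times and spans are
    local to each statement. Scoping is forward-only: the carried-forward
    time is the last time of any earlier statement.
    """
    carried: TemporalTerm | None = UNSPECIFIED
    out: list[tuple[TaggedSpan, TemporalTerm | None]] = []
    for _text, times, spans in statements:
        times = sorted(times, key=lambda t: t.start)
        for span in spans:
            if not times:
                out.append((span, carried))
                continue
            covering: TemporalTerm | None
            if len(times) == 1:
                # rule 1: a single time covers the whole statement
                covering = times[0]
            elif span.start < times[0].start:
                # rule 2 prefix before the first time: carried-forward if any
                covering = carried if carried is not UNSPECIFIED else times[0]
            else:
                covering = times[0]
                for t in times:
                    if t.start <= span.start:
                        covering = t
                    else:
                        break
            out.append((span, covering))
        if times:
            carried = times[-1]
    return out
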