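"""Extract temporal terms and assign each event its time.

Three scoping rules over period-delimited statements: a lone time covers
its whole statement; multiple times split the statement at their start
offsets; a timeless statement inherits the previous statement's last time.
"""

from emrtriples import Category, LexiconSet, tag_terms
from emrtriples.temporal import (
    UNSPECIFIED,
    assign_time_scopes,
    extract_temporal_terms,
    split_statements,
)

lex = LexiconSet()
for t in ["咳嗽", "发热", "呕吐"]:
    lex.add_term(t, Category.SYMPTOM)

doc = "约3个月前咳嗽，昨晚发热。呕吐。"
statements = [
    (stmt, extract_temporal_terms(stmt), tag_terms(stmt, lex))
    for _, stmt in split_statements(doc)
]

print(doc)
for stmt, times, _ in statements:
    print(f"  statement {stmt!r}: times {[t.surface for t in times]}")
for span, time in assign_time_scopes(statements):
    label = time.surface if time is not UNSPECIFIED else "UNSPECIFIED"
    print(f"  {span.surface} -> {label}")

# 咳嗽 is covered by 约3个月前 (rule 2), 发热 by 昨晚 (rule 2), and the
# timeless second statement's 呕吐 inherits 昨晚 (rule 3).
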