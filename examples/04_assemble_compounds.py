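"""Assemble compound terms from body-part enumerations and directional
prefixes.

"口腔、黏膜出血" abbreviates two findings sharing the suffix 出血; whether
a non-adjacent pair (B, D) may combine is decided by the corpus-estimated
probability of B being immediately followed by D. Directional modifiers
(左侧, 双, ...) extend a known term via a three-character look-back.
"""

from emrtriples import (
    Category,
    LexiconSet,
    assemble_enumeration,
    build_adjacency_table,
    expand_directional_prefix,
    tag_terms,
)
from emrtriples.tagger import TaggedSpan

lex = LexiconSet()
for term, cat in [
    ("口腔", Category.BODY_PART),
    ("黏膜", Category.BODY_PART),
    ("出血", Category.SYMPTOM),
    ("肾结石", Category.DISEASE),
]:
    lex.add_term(term, cat)

# adjacency statistics from a tiny training corpus
corpus = ["口腔出血。黏膜出血。口腔痛。"]
table = build_adjacency_table(corpus, lex, threshold=0.01)
print("P(出血 follows 口腔) =", table.prob("口腔", "出血"))

stmt = "口腔、黏膜出血"
spans = tag_terms(stmt, lex)
for compound in assemble_enumeration(stmt, spans, table, lex):
    print(f"  assembled: {compound.surface} ({compound.category.value})")

doc = "发现双肾结石"
span = TaggedSpan("肾结石", Category.DISEASE, 3, 6)
expanded = expand_directional_prefix(doc, span)
print(f"  expanded:  {span.surface} -> {expanded.surface}")

# Both 口腔出血 and 黏膜出血 are emitted because the corpus supports the
# non-adjacent pair; 双肾结石 extends the known disease 肾结石.
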