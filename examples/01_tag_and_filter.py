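"""Tag medical terms in a short narrative and separate events from
negated/future mentions.

The tagger is a recursive longest match against the categorized lexica;
the filter demotes symptoms, procedures and clinical tests that follow a
negation ("no chills") or a future marker ("scheduled for ...") inside
the same clause.
"""

from emrtriples import Category, LexiconSet, filter_events, tag_terms

lex = LexiconSet()
for term, cat in [
    ("咳嗽", Category.SYMPTOM),
    ("恶寒", Category.SYMPTOM),
    ("头孢呋", Category.DRUG),
    ("前列腺电切术", Category.PROCEDURE),
]:
    lex.add_term(term, cat)

doc = "咳嗽3天，无恶寒，给予头孢呋，拟行前列腺电切术。"
spans = filter_events(doc, tag_terms(doc, lex))

print(doc)
for sp in spans:
    flag = "event" if sp.is_event else "not an event"
    print(f"  [{sp.start:2d},{sp.end:2d}) {sp.surface:8s} {sp.category.value:12s} {flag}")

# Expected: 咳嗽 and 头孢呋 are events the patient experienced; 恶寒 is
# negated and 前列腺电切术 is scheduled but not performed, so neither is an
# event — they will never surface in an extracted triple.
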