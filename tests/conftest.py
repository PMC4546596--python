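import pytest

from emrtriples.lexicon import Category, LexiconSet, Provenance


@pytest.fixture
def sym_lex() -> LexiconSet:
    """Symptom-only lexicon for the temporal scoping fixtures."""
    lex = LexiconSet()
    for t in ["咳嗽", "发热", "呕吐", "腹泻", "头晕", "乏力"]:
        lex.add_term(t, Category.SYMPTOM)
    return lex


@pytest.fixture
def toy_lexica() -> LexiconSet:
    """A small hand-built lexicon covering all six categories."""
    lex = LexiconSet()
    for term, cat in [
        ("上呼吸道感染", Category.DISEASE),
        ("输尿管结石", Category.DISEASE),
        ("肾结石", Category.DISEASE),
        ("咳嗽", Category.SYMPTOM),
        ("咳痰", Category.SYMPTOM),
        ("恶寒", Category.SYMPTOM),
        ("出血", Category.SYMPTOM),
        ("头孢呋", Category.DRUG),
        ("阿莫西林", Category.DRUG),
        ("口腔", Category.BODY_PART),
        ("黏膜", Category.BODY_PART),
        ("腹", Category.BODY_PART),
        ("前列腺电切术", Category.PROCEDURE),
        ("肺功能", Category.CLINICAL_TEST),
    ]:
        lex.add_term(term, cat, Provenance.CORE)
    return lex
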