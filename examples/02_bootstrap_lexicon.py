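"""Recover unknown drug names from a corpus by pattern iteration.

The generator withholds 20 drug terms from the core lexicon but writes
them into stereotyped contexts (给予…抗感染, 予…口服, 服…后缓解). Each
bootstrapping round harvests character-context patterns around known drug
occurrences, keeps the selective and precise ones (PS > PST, PP > PPT),
and accepts new terms extracted by more than one kept pattern (TF > TFT).
"""

from emrtriples import Category, bootstrap
from emrtriples.bootstrap import BootstrapConfig
from emrtriples.synthetic import SynthConfig, generate_corpus, make_toy_lexica

cfg = SynthConfig(seed=11, n_docs=500)
lex, planted = make_toy_lexica(cfg)
corpus = [d.text for d in generate_corpus(cfg, lex, planted)]

enriched, history = bootstrap(
    corpus, lex, Category.DRUG, BootstrapConfig(pst=3, ppt=0.5, tft=1)
)

added = enriched.entries[Category.DRUG] - lex.entries[Category.DRUG]
plant = set(planted[Category.DRUG])
print(f"core drug lexicon: {len(lex.entries[Category.DRUG])} terms, "
      f"{len(plant)} unknowns planted in {len(corpus)} documents")
for h in history:
    print(f"  round {h.iteration}: kept {h.n_patterns_kept} patterns, "
          f"added {h.n_terms_added} terms")
print(f"recovered {len(added & plant)}/{len(plant)} planted drugs, "
      f"{len(added - plant)} spurious accretions")
print("examples:", sorted(added & plant)[:5])

# The added-terms-per-round sequence drops to zero: the iteration
# converges once every recoverable term has been accrued.
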