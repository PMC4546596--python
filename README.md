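# emrtriples

Structured **(time, event, description)** triple extraction from free-text
Chinese clinical narratives.

Chinese inpatient notes — in particular the History of Present Illness —
are concise, comma-dense and stylized; notes from Traditional Chinese
Medicine practice can read like classical Chinese, which defeats word
segmenters and POS taggers trained on modern news text. `emrtriples`
therefore works at the **character** level and is driven by dictionaries
and corpus statistics rather than by syntactic analysis. It converts a
narrative such as

> 3天前出现咳痰，色黄质粘，今晨查肺功能…

into records of the form *(3天前, 咳痰, 色黄质粘)*: when an event happened,
what it was, and an optional free-text elaboration (a sputum's quality, a
spirometry reading). The package is aimed at medical-informatics engineers
and researchers mining real-world evidence from EMR text.

## Method

1. **Categorized lexica.** Six term dictionaries (disease, symptom, drug,
   body part, procedure, clinical test) with per-term provenance.
2. **Pattern-iteration bootstrapping.** The disease and drug lexica are
   grown from the corpus without annotation. Around every tagged
   occurrence, up to nine literal character-context patterns
   `left⟨SLOT⟩right` (1–3 characters per side) are harvested and scored:
   *pattern selectivity* PS = number of unique already-known terms the
   pattern extracts, *pattern precision* PP = PS / (unique terms
   extracted). Patterns with PS > PST and PP > PPT extract candidate
   terms; a candidate extracted by more than TFT kept patterns is accrued.
   Iterate to convergence.
3. **Compound-term assembly.** Enumerations `B₁、B₂、D` / `B、D₁、D₂`
   sharing a body-part prefix are expanded (口腔、黏膜出血 → 口腔出血 +
   黏膜出血), gated by the corpus probability P(D follows B) so that
   腹痛、呕吐 never yields 腹呕吐. Directional/extensional modifiers
   (左侧, 双, …) extend known terms via a three-character look-back.
4. **Longest-match tagging + event filter.** Recursive longest match with
   boundary-character blocking; negated (无/拒绝/否认/未见…) and future
   (拟/建议…) mentions of symptoms, procedures and tests are kept as spans
   but are not events.
5. **Temporal extraction and scoping.** A nine-part grammar
   `(Pre-AW)? Numbers (Unit)? TemporalUnit (Post-AW)? Preposition` plus
   day references and six idioms (昨夜, 昨晚, 今夜, 今晚, 今早, 今晨);
   three scoping rules assign every event a covering time within
   period-delimited statements, carrying times forward across statements.
6. **Description linking.** Uncovered clause segments become candidate
   descriptions; every same-statement (event, candidate) pair is
   classified by a linear SVM over eight features — character context
   windows, a digit flag, between-counts, the event category, and the
   **Normalized Google Distance**

   NGD(x, y) = [max(log f(x), log f(y)) − log f(x, y)] / [log M − min(log f(x), log f(y))]

   computed from a pluggable frequency source (shipped default: document
   frequencies of the training corpus).

A seeded synthetic-corpus generator with complete gold structure
(`emrtriples.synthetic`) stands in for clinical data, which cannot be
redistributed; see `docs/methods.md` for what it does and does not
emulate.

## Worked example

```bash
python examples/01_tag_and_filter.py
```

```
咳嗽3天，无恶寒，给予头孢呋，拟行前列腺电切术。
  [ 0, 2) 咳嗽       symptom      event
  [ 6, 8) 恶寒       symptom      not an event
  [11,14) 头孢呋      drug         event
  [17,23) 前列腺电切术   procedure    not an event
```

咳嗽 (cough) and 头孢呋 (cefuroxime) are events the patient experienced;
恶寒 (chills) is negated and the prostate resection is merely scheduled,
so neither may anchor a triple. The other examples cover lexicon
bootstrapping (`02`), temporal scoping (`03`), compound assembly (`04`),
description linking versus the adjacency baseline (`05`) and the full
pipeline (`06`). Running `python examples/06_end_to_end.py` prints, for a
500-document synthetic corpus:

```
500 documents, 2560 gold triples
bootstrap planted-drug recall: 1.000
span exact F1:                 1.000
time-link accuracy:            1.000
triple exact F1:               1.000
```

together with one document's extracted triples. A thin CLI mirrors the
stages: `emrtriples synth|enrich|tag|extract|eval --help`.

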