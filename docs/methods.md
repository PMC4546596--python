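# Methods

This note documents the models and procedures implemented in
`emrtriples`, the parameters that matter, the synthetic study conditions,
and the design decisions taken where the design was genuinely open.

## Problem setting and assumptions

The package converts free-text Chinese clinical narratives into
(time, event, description) triples. Two assumptions shape everything:

* **No trustworthy segmentation.** General-purpose Chinese segmenters and
  POS taggers fail on clinical prose, so every "word window" in the
  framework — bootstrap pattern contexts, the directional look-back, the
  linker context features — is defined over *characters*, punctuation
  included.
* **A narrative describes one patient.** Every recognized term denotes an
  event the patient experienced, except symptoms, procedures and clinical
  tests that are negated or marked as future within their clause.
  Disease and drug mentions always count as events; body-part mentions
  never do on their own (they feed compound assembly).

## Lexica

Six exact-match, case-sensitive dictionaries. Terms are raw Unicode with
whitespace stripped on load; no width or case folding is applied to lexica
(any normalization belongs to an optional document pre-pass, so that the
stored surface forms stay authoritative). A term may live in several
categories; each (term, category) pair carries one provenance tag
(`core`, `pattern_iteration`, `body_part_assembly`, `prefix_update`) and
the first origin wins on re-insertion.

## Pattern-iteration bootstrap

Per round: tag the corpus with the current lexicon of the target category;
harvest the ≤ 9 context patterns (left/right windows of 1–3 characters,
truncated at document boundaries, deduplicated) around every occurrence;
score each pattern over the corpus; keep patterns with `PS > PST` and
`PP > PPT` (strict, as are all three thresholds); accept filler terms
extracted by more than `TFT` kept patterns. "Known" at round *k* means in
the core lexicon or accepted before round *k*. Stops when a round accepts
nothing or after `max_iterations` (default 10).

Slot fillers are **shortest-match per left-anchor occurrence**: the filler
runs from the anchor to the first occurrence of the right context, must be
1–`max_term_len` characters (default 10) and may not contain
statement/clause punctuation (。，、；：!？ and ASCII variants). Rejection
per anchor is final, because any longer filler at the same anchor contains
the same defect. Unbounded greedy matching would swallow whole clauses;
the bound and the punctuation bar are the two guards.

Tuned operating points: `PST=7, PPT=0.7` for disease and
`PST=6, PPT=0.85` for drug lexica, `TFT=1` ("extracted by more than one
pattern") — selectable per corpus by `grid_search_thresholds`, whose
default grids are PST 3–10 step 1 and PPT 0.30–0.90 step 0.05 (104
configurations), maximizing exact-match tagging F1 on a tuning set with
ties broken toward the more conservative (higher PPT, then higher PST)
setting. Only disease and drug lexica are bootstrapped by default: the
other categories' contexts (e.g. the colon after a test name) are not
selective. On the synthetic corpus the operating point is
`PST=3, PPT=0.5, TFT=1`: its core drug inventory outnumbers the planted
unknowns roughly 2:1 in every shared context, which caps attainable
pattern precision near 0.7, so the corpus-appropriate PPT sits below it.

Patterns are re-harvested each round from *all* tagged occurrences of the
slot category (not only core-term occurrences); provenance tags allow
filtering either policy after the fact.

## Compound-term assembly

For enumerations `B₁…BₙD` and `BD₁…Dₙ` (members separated only by 、/，),
compounds BᵢD / BDⱼ take the D term's category. The textually adjacent
pair is always emitted (unless the concatenation is already a lexicon
term); non-adjacent pairs require `P(D follows B) > threshold` (default
0.01). The probability is conditioned on B's total occurrence count —
`adjacent(B, D) / count(B)` — a denominator chosen because it is
directional, bounded in [0, 1] and estimable from the corpus alone. D
ranges over disease/symptom/procedure/clinical test; drug is excluded
because compound drug names do not take body-part prefixes. Non-adjacent
compounds are, by construction, not contiguous substrings of the
statement; their spans cover the component range and their surfaces are
the concatenations. Assembled terms are persisted to the lexicon by
default (recognition-only use is a flag away), mirroring the growth of
the body-part-prefixed vocabulary.

The directional/extensional vocabulary (左, 右, 双, 侧, 上, 下 and
two-character combinations) ships as an editable config; the look-back is
three characters, and the longest window suffix expressible as a
concatenation of modifiers is absorbed. Expansion happens once per span;
the pipeline tracks expanded spans so re-expansion is a no-op.

## Tagging and the event filter

Tagging is the recursive longest match: candidate lengths from longest to
shortest, start positions left to right, a candidate admitted only when
neither boundary character is already tagged. The boundary-character
check (cheaper than a full overlap check, and sufficient because longer
candidates always go first) defines the tagger's exact semantics, which
the test suite pins to an independent brute-force oracle.
Multi-dictionary hits emit one span
per category at the same offsets — no category priority is invented.

Negation prefixes (无, 拒绝, 否认, 未见) and future markers (拟, 建议)
demote symptom/procedure/clinical-test spans when they occur *earlier in
the same comma-delimited clause*; clause-local precedence is the
narrowest reading of "prefixed with". Both marker lists are config.

## Temporal terms and scoping

Two grammar forms plus six idioms, all built from editable vocabularies;
numbers cover Arabic digits and Chinese numerals (一…十, 两, 半, …).
Extraction is leftmost-longest, non-overlapping. No calendar
normalization is performed — events link to temporal *surface* terms, and
durations confused with anchors remain an open error mode. Scoping rules
over period-delimited statements: (1) a lone time covers its whole
statement, including text before it; (2) with several times, each covers
from its start to the next time's start, and the prefix before the first
time falls to the carried-forward time when one exists (else the first
time — the rule-3-consistent choice for a case the rules leave open);
(3) timeless statements inherit the last time of any earlier statement,
else UNSPECIFIED. Scoping is forward-only. Statement boundary is 。 by
default (！？ via config).

## Description linking

Candidates are the maximal uncovered character runs within clauses,
stripped of punctuation; candidates overlapping non-event spans or
containing stopwords (入院, 出院, 住院, 就诊, 治疗 by default) are
discarded. Pairs are generated within one statement only — the same unit
that bounds temporal coverage — and linking is many-to-many.

The classifier is a linear-kernel SVM (C=1, balanced class weights,
seeded) over eight features: four 3-character context windows (sentinel
padded at boundaries), a digit flag, NGD, counts of terms / candidates /
commas strictly between the pair, and the event category. Context windows
and the category are one-hot encoded by a `DictVectorizer` fitted on
training data (unseen values become the all-zero bucket); the stacked
matrix is max-abs scaled, which leaves the one-hot block in {0, 1} while
bringing the counts and the NGD cap onto a comparable scale. The encoding
of the context "words" is a package choice; the feature list itself is
fixed.

NGD undefined cases (any zero frequency, or a term in every indexed unit)
map to a finite cap (default 10) so feature vectors stay finite; natural
log is used (the ratio cancels the base). The frequency provider is
pluggable: the default counts *statement*-level document frequencies of
the training corpus — the narrowest co-occurrence unit the framework
defines, which keeps the relatedness signal sharp at desk scale — and a
cached-count backend can replay search-engine hit counts offline, since
live query APIs are neither stable nor reproducible.

## Synthetic study conditions

The generator (`emrtriples.synthetic`) emulates the structural properties
the methods depend on: 3–6 period-delimited statements per document;
temporal phrases (relative durations, day references, idioms) heading
80% of statements, 15% of symptom statements carrying two times; negation
and future statements at 5% each; drug statements in three shared
contexts (给予…抗感染, 予…口服, 服…后缓解); 45 core + 20 planted drugs,
scheduled so every core drug appears in every context and every planted
drug in at least two; descriptions on 55% of symptom/test statements,
drawn from two dedicated phrases per event term so that corpus
co-occurrence is genuinely informative (the sharp end of
"category-conditioned" description vocabulary).

Per-category character inventories are pairwise disjoint and disjoint
from all template, temporal and description characters, and terms within
a category share a fixed length; this guarantees longest-match tagging
reproduces the gold spans exactly. That guarantee is precisely what real
corpora lack — green tests on this corpus bound engineering correctness
(offset bookkeeping, rule implementations, learning machinery), not
clinical accuracy; abbreviation variants, typos, segmentation ambiguity
and cross-category homography are all absent. The generator also exports
its template connector vocabulary as a recommended stoplist, playing the
same role for this corpus that the common-EMR-word list plays for real
notes.

Reference problem sizes (in `emrtriples.experiments`, all seeded): 500
documents for bootstrap recovery and the end-to-end run; 220 documents
(≈1,000 statements) per linker repetition, five repetitions with a 75/25
document split. These sizes make every experiment run in seconds while
keeping a few thousand gold triples in play. The end-to-end protocol —
enrich, train the linker on the 75% split, extract everywhere — trains on
synthetic gold pairs (positives are generated links, negatives all other
same-statement pairs), so no human labels enter anywhere.

## Numerical and degenerate-input choices

* Strict inequalities for PST/PPT/TFT; patterns that extract nothing have
  undefined precision and are dropped.
* NGD requires M ≥ 2; a non-positive denominator (term in every unit)
  returns the cap; results clamp to [0, cap].
* Empty statements, empty lexica, documents without periods, and
  single-span enumerations all degrade to empty outputs rather than
  errors; cross-statement featurization and single-class training raise.
* Evaluation: F1 = 2PR/(P+R) with 0 when P+R=0; inexact mode relaxes
  span offsets to same-category overlap; triple-level description match
  is exact interval equality (an overlap variant sits behind a flag,
  since partial description credit is otherwise undefined).

## Known limitations

* The boundary-character blocking of the tagger can, in principle, let a
  short term nest strictly inside the untagged middle of a longer span's
  region; this is inherent to the boundary-check formulation and is
  pinned by the oracle tests.
* Compound assembly does not validate compounds semantically; it is
  gated only by corpus adjacency statistics.
* Temporal durations vs. anchors are not disambiguated, and no absolute
  timeline is constructed.
* Headline scores on the synthetic corpus (near-perfect span and triple
  F1) reflect the generator's collision-free construction and should not
  be read as expected performance on clinical text.
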