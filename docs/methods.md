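# Methods

This note records the models, rules and numeric defaults behind
`postopqa`, the reasoning where the design was genuinely open, and what
the synthetic test conditions do and do not establish about real data.

## Text primitives

Tokens are maximal runs of letters (internal hyphens/apostrophes kept:
"pain-free", "can't") or digit groups (internal decimal points kept:
"3.5"), lowercased, with character offsets into the source. Sentence
segmentation is rule-based: a `.!?` run ends a sentence when followed by
whitespace plus a capital/digit (or end of text), with a small
abbreviation list ("Dr.", "e.g.", ...) and the no-whitespace rule for
decimals. Rule-based segmentation was chosen over model-based for
determinism and zero downloads; it under-segments unusual prose, which is
acceptable because the knowledge base is controlled text.

**Fuzzy Jaccard.** The package's core similarity is set Jaccard over
unique tokens where two tokens match if equal or if the normalized
edit-distance similarity `1 − lev(a,b)/max(|a|,|b|)` reaches a threshold
(default **0.85** — tolerates plural/inflection variants such as
"dressing"/"dressings" at 8/9 ≈ 0.89 without matching unrelated words).
Pairing is greedy in descending similarity, each token used once; greedy
is deterministic and, as a maximal matching, recovers at least half the
optimal match count — the tests compare it against an optimal-assignment
oracle. Two empty token sets score 1.0 (degenerate identity). "Fuzzy" has
no canonical construction in this metric family; the edit-distance form
is this package's declared choice.

## Ingestion

Chunks are the retrieval unit: greedy sentence-packing up to a
**500-character** limit, never splitting a sentence, with no overlap
(overlapping windows would duplicate content across embeddings and dilute
retrieval precision). A single oversize sentence becomes its own chunk,
flagged `overflow`, because splitting it would destroy the grounding
unit. A paragraph break closes the current chunk once it is ≥ 60% full — a
cheap proxy for layout awareness, configurable off. Chunk count is
monotone non-increasing in the limit for pure greedy packing (property
tested on single-paragraph documents; the paragraph rule can interact
with the limit in contrived multi-paragraph cases).

## Embeddings and index

The default embedding backend is a seeded token-hash superposition: each
token maps through a keyed BLAKE2 hash to a fixed pseudo-random unit
vector in **768** dimensions; a text embeds as the L2-normalized sum of
its token vectors weighted by sublinear term frequency `1 + log tf`. A
small function-word stopword list (articles, auxiliaries, quantifiers,
light verbs such as "keep/get/check", temporal adverbs) is dropped before
hashing so that shared syntax alone does not create affinity between
unrelated texts — the bag-of-tokens analogue of what a trained sentence
encoder learns to ignore. The backend is exact-match lexical semantics:
it has no notion of synonymy, which is the main respect in which the
synthetic conditions are easier than real embeddings. Any external
embedding service plugs in behind the same `embed(text) -> vector`
contract; empty/stopword-only text yields the zero vector, which the
index and retrieval treat as a degenerate-query flag.

The vector index is a from-scratch HNSW graph (level scale `1/ln M`,
greedy descent through upper layers, beam search of width `ef` at the
target layer, 2M links at layer 0). Defaults: **M = 32, efConstruction =
200, efSearch = 100**; efSearch must exceed the query `k`. Insertion
order is fixed by chunk-id sort and level draws come from the seeded
generator, so builds are reproducible. With `ef` equal to the corpus size
the layer-0 beam search exhausts the connected graph and equals exact
k-NN (tested); at 1,000 points recall@10 ≥ 0.95 against brute force
(tested).

## Retrieval

Serving retrieval embeds the query, takes the ANN **top-10** by cosine,
computes Okapi BM25 (**k1 = 1.5, b = 0.75**, the canonical defaults;
corpus statistics precomputed over all chunks, scores evaluated only on
the candidates — re-ranking, not full-corpus lexical search), min–max
normalizes both score lists within the candidate set, fuses with
`alpha = 0.5`, and returns the **top-3** as the evidence set, ties broken
by chunk id. Min–max + convex combination is the simplest auditable
fusion and makes the ranking invariant to affine rescaling of raw BM25
scores. The full top-10 trace is retained on every evidence set for
auditing.

## Answer generation and gates

The augmented prompt is a pure function of (fixed role instruction,
question, evidence passages tagged with chunk ids), checked against a
6,000-character context budget with rank-3-first truncation.

The default generator is extractive: evidence sentences are scored by
fuzzy Jaccard against the question, the top **5** at or above a floor of
**0.05** are kept and presented in evidence-rank-then-position order.
Selection by score (rather than first-come) keeps generic lead-in
sentences from displacing the answering fact. The generator contract is
synchronous text-in/text-out; an LLM adapter lives outside the tested
core, and the gates below are generator-agnostic.

**Grounding gate.** Every draft sentence receives a confidence equal to
its best fuzzy Jaccard against any evidence unit, where units are each
evidence chunk's full token set *and* each chunk sentence's token set.
The sentence-level units matter: a short claim copied verbatim from a
long chunk would score only `|sentence|/|chunk|` against the whole chunk
and could fail the gate despite being perfectly supported; against its
source sentence it scores 1.0. A draft is accepted only if **all**
sentences reach the threshold (default **0.35**); the mean-score variant
would let one fabricated sentence hide behind several grounded ones.

**Heuristic gate.** Every numeral in the draft (commas stripped, trailing
decimal zeros dropped) must occur as a numeral in the evidence; bracketed
citation numbers and "et al." with no evidence counterpart are flagged.
Comparison is deliberately literal — no unit conversion, so "2 weeks"
does not license "14 days"; a conversion engine would silently endorse
exactly the class of plausible-looking fabrications the gate exists to
catch. Number-word matching (one–ten) is available behind a config flag,
off by default.

Any gate failure yields a fixed safe-handoff template (status
`rejected_grounding` / `rejected_heuristic`), an empty draft yields
`fallback_handoff`, and internal errors are converted to
`fallback_handoff` — the pipeline is total: every query receives a
response object.

## Safety routing

Routing precedes generation, with precedence escalate > decline > answer.
Both detectors are lexicon/pattern-based: a safety gate must be
deterministic and its trigger inventory reviewable as config.

*Escalation*: a query escalates iff any red-flag phrase (breathing
difficulty, uncontrolled/soaking bleeding, chest pain, high fever, loss
of consciousness, spreading-infection signs, calf swelling) matches as a
sliding token window with per-token fuzzy tolerance 0.85 (so "cant
breathe" matches "can't breathe").

*Out-of-scope*: a query is declined iff its best raw dense cosine against
the knowledge base is below the scope floor (**0.15**) AND it contains no
medical-domain token. Two notes. First, the *raw* cosine is used rather
than the fused re-ranking score: fused scores are min–max normalized
within the candidate set, so the top candidate scores ≈ 1 by construction
and carries no absolute-affinity information. Second, the conjunction
biases toward answering: wrongly declining a medical question is worse
than retrieving weak evidence for it, because the grounding gate still
protects the answer downstream. A `calibrate_scope_floor` helper computes
the 5th percentile of in-scope best scores for data-driven recalibration;
with the synthetic corpus the in-scope/out-of-scope score distributions
are well separated around the 0.15 default (out-of-scope maxima ≈ 0.13,
in-scope queries carry medical vocabulary regardless).

## Synthetic study conditions

The corpus factory defines the test conditions; it is not tunable per
run. Shape invariants (any seed): 20 topic documents; 250 base queries —
10 in-scope per topic (200), 40 non-medical (finance / travel booking /
entertainment / tech support), 10 red-flag escalation scenarios — each
with exactly two rule-based paraphrases (leading-phrase synonym
substitution; trailing-clause reordering or register shift), for 750
total. Paraphrases are label-blind string operations that never touch
red-flag phrases. Each topic document is assembled from ten parameterized
fact sentences (one per question schema: timing, duration, frequency,
monitoring, method, restriction, supplies, comfort, when-to-call,
expectations) carrying explicit numerals drawn from clinically plausible
ranges by the seeded generator; documents are ≥ 1,100 characters so the
500-character chunker always produces multiple chunks. Every in-scope
query's gold passage is its generating fact sentence verbatim — grounded
by construction — and its gold reference adds a fixed safety-net
sentence so reference answers are not character-identical to evidence.
Out-of-scope templates contain no clinical vocabulary and no topic-name
vocabulary; that separation is a stated corpus invariant (the category
label must be unambiguous), not a tuned threshold.

The rating simulator draws a three-reviewer panel per base query:
consensus correct with probability 0.984, a 2-vs-1 split with probability
0.02, and Likert/SSI scores from discrete distributions whose means are
4.83 (completeness), 4.49 (consistency) and 2.68 (SSI 0–3). The SSI
rubric is treated as gated-cumulative (sensible +1; then specific +1;
then interesting +1), which is how "three dependent dimensions" is read
here.

What passing these conditions does *not* show: robustness to real
patient language (misspellings, dialect, ambiguity), semantic retrieval
beyond lexical overlap, or the behaviour of a generative LLM behind the
gates. The synthetic corpus establishes the *mechanics* — routing
precedence, gate soundness, totality, determinism, metric arithmetic —
not clinical performance.

## Evaluation framework

*Classification*: micro-averaged accuracy/precision/recall/F1 from a
pooled confusion matrix; precision with no predicted positives is
reported as undefined, never 0. Both Wald and Wilson 95% intervals are
reported because published proportions in this literature rarely state
their interval construction and the two differ visibly at n = 250.
Topic-level accuracy uses the unweighted topic mean with sample SD (n−1).

*Reliability*: Fleiss' kappa (pooled-marginal chance correction),
pairwise Cohen's kappa with mean and range, Krippendorff's alpha via the
coincidence matrix (nominal 0/1 distance; ordinal squared cumulative
margin; missing ratings allowed), and two-way random-effects ICC —
ICC(2,1) and ICC(2,k) from the ANOVA mean squares. Degenerate inputs
(single shared category, zero denominators) return explicit
undefined-flags. Note that Fleiss' kappa with two raters is Scott's pi,
which equals Cohen's kappa only when the raters share marginals; the
tests encode that exact relationship. Each coefficient is verified
against an independent implementation (statsmodels, scikit-learn,
pingouin) or a brute-force pair-enumeration oracle.

*Groundedness*: an evaluation-grain retriever re-chunks the knowledge
base at **300 words**, takes the dense top-2k with maximal-marginal-
relevance diversification (**lambda = 0.7**), unions the BM25 top-2k, and
fuses to the top **k = 4**. Context precision = fraction of retrieved
chunks whose fuzzy Jaccard with the gold passage reaches the support
threshold (**tau = 0.35**, independently configurable from the serving
gate); context recall = fraction of gold-passage sentences recovered;
faithfulness = fraction of answer sentences supported; hallucination
rate = 1 − faithfulness. Batch values are means of item values.

*Fluency*: BLEU (orders ≤ 4, uniform weights, brevity penalty, add-one
smoothing for zero higher-order counts, hard zero on zero unigram
overlap), ROUGE-1/2 n-gram F1, ROUGE-L LCS F1, and an embedding-F1
"BERTScore analogue" computed by greedy token-embedding matching under
the hashed backend — explicitly *not* comparable to published BERTScore
numbers; a real encoder can be plugged into the same slot.

*Readability*: FKGL = 0.39·(words/sentence) + 11.8·(syllables/word) −
15.59 and FRE = 206.835 − 1.015·(words/sentence) − 84.6·(syllables/word),
with a deterministic syllable counter (vowel groups, silent final "e"
except consonant-"le", small exception table). Reading-level bins at FKGL
≤ 12 (high school or below), (12, 16] (college), > 16 (college graduate)
— three-bin summaries of this kind rarely state their boundaries, so
these are declared here.

## Problem sizes and numerics

The default study runs at its native scale: 20 documents (~70 serving
chunks), 750 queries, 250 rated items; the full corpus answers in a few
seconds on one core. Recall and exactness properties for the HNSW index
are checked at 1,000 and 200 points respectively — large enough for the
graph structure to matter, small enough to compare against brute force.
All randomness flows from explicit seeds (corpus content, level draws,
rating panel); there is no wall-clock or OS entropy anywhere, which is
what makes the end-to-end byte-determinism test possible. Ties are broken
lexicographically by id throughout (retrieval, fusion, MMR by index) so
orderings are total.

## Known limitations

- The hashed embedding is lexical; paraphrases with zero token overlap
  retrieve nothing. The architecture treats this as an adapter boundary,
  not a modelling claim.
- The extractive generator cannot synthesize across chunks or simplify
  language; readability of its output simply reflects the knowledge base.
- The out-of-scope filter depends on the medical lexicon and the scope
  floor; domains adjacent to the knowledge base (e.g., veterinary wound
  care) would be answered, gated only by grounding.
- Escalation detection is English-only and phrase-based; negations ("I am
  not bleeding") are routed conservatively to escalation.
- The sentence splitter and syllable counter are rule-based
  approximations; both are deterministic but imperfect on edge cases.
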