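"""Automated response-quality battery.

Three families of metrics over batches of (answer, reference, gold passage)
triples:

* **Groundedness** via a two-stage hybrid evaluation retriever — dense
  search with maximal-marginal-relevance (MMR) diversification over
  300-word chunks, unioned with BM25 candidates and fused — feeding three
  fuzzy-Jaccard metrics: context precision (retrieved chunks supporting the
  gold passage), context recall (gold-passage sentences recovered) and
  faithfulness (answer sentences supported); hallucination rate is
  1 - faithfulness.
* **Fluency**: BLEU (orders <=4, uniform weights, brevity penalty, add-one
  smoothing for short texts), ROUGE-1/2 n-gram F1, ROUGE-L LCS F1, and a
  BERTScore-style greedy token-embedding F1 computed with the hashed
  backend — a *hash-embedding analogue*, not comparable to published
  BERTScore numbers.
* **Readability**: word/sentence structure counts, rule-based syllable
  counting, Flesch-Kincaid grade level and Flesch reading ease, binned into
  high-school/college/graduate reading levels.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .index_retrieval import BM25Corpus, HashedEmbeddingBackend, minmax_normalize
from .kb_ingest import SourceDocument
from .textcore import fuzzy_jaccard, split_sentences, tokenize

# ---------------------------------------------------------------------------
# evaluation retriever (300-word chunks, dense+MMR then BM25 union)
# ---------------------------------------------------------------------------


def chunk_by_words(doc: SourceDocument, chunk_words: int = 300) -> list[tuple[str, str]]:
    """Non-overlapping ~``chunk_words``-word, sentence-respecting chunks."""
    sentences = split_sentences(doc.body)
    chunks: list[tuple[str, str]] = []
    current: list[str] = []
    count = 0
    for sent in sentences:
        n = len(tokenize(sent))
        if current and count + n > chunk_words:
            chunks.append((f"{doc.doc_id}/e{len(chunks):03d}", " ".join(current)))
            current, count = [], 0
        current.append(sent)
        count += n
    if current:
        chunks.append((f"{doc.doc_id}/e{len(chunks):03d}", " ".join(current)))
    return chunks


def mmr_select(
    query_vec: np.ndarray,
    candidate_vecs: np.ndarray,
    k: int,
    lam: float = 0.7,
) -> list[int]:
    """Greedy maximal-marginal-relevance selection.

    ``MMR(d) = lam * sim(q, d) - (1 - lam) * max_{d' in S} sim(d, d')``;
    with lam = 1 this is pure similarity order.  Ties break on index.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    sims = candidate_vecs @ query_vec
    selected: list[int] = []
    remaining = list(range(len(candidate_vecs)))
    while remaining and len(selected) < k:
        if not selected:
            scores = [lam * sims[i] for i in remaining]
        else:
            sel_vecs = candidate_vecs[selected]
            scores = [
                lam * sims[i] - (1.0 - lam) * float(np.max(sel_vecs @ candidate_vecs[i]))
                for i in remaining
            ]
        best = max(range(len(remaining)), key=lambda j: (scores[j], -remaining[j]))
        selected.append(remaining.pop(best))
    return selected


class EvalRetriever:
    """Two-stage hybrid retriever over the evaluation-grain chunking.

    Distinct from the serving index: the knowledge base is re-chunked at
    ~300 words, stage 1 takes the dense top-2k with MMR diversification,
    stage 2 unions in the BM25 top-2k, and the union is fused (min-max +
    convex combination) down to the top k.
    """

    def __init__(
        self,
        docs: list[SourceDocument],
        backend: HashedEmbeddingBackend | None = None,
        chunk_words: int = 300,
        k: int = 4,
        mmr_lambda: float = 0.7,
        alpha: float = 0.5,
    ) -> None:
        if not docs:
            raise ValueError("empty knowledge base")
        self.k = k
        self.mmr_lambda = mmr_lambda
        self.alpha = alpha
        self.backend = backend or HashedEmbeddingBackend()
        self.ids: list[str] = []
        self.texts: dict[str, str] = {}
        for doc in sorted(docs, key=lambda d: d.doc_id):
            for cid, text in chunk_by_words(doc, chunk_words):
                self.ids.append(cid)
                self.texts[cid] = text
        self.vectors = np.array([self.backend.embed(self.texts[c]) for c in self.ids])
        self.bm25 = BM25Corpus({c: tokenize(self.texts[c]) for c in self.ids})

    def retrieve(self, question: str) -> list[tuple[str, str]]:
        """Return the fused top-k (chunk_id, text) evidence for a question."""
        qvec = self.backend.embed(question)
        sims = self.vectors @ qvec
        stage = min(2 * self.k, len(self.ids))
        # stage 1: dense + MMR diversification
        order = np.argsort(-sims, kind="stable")[: max(4 * self.k, stage)]
        mmr_idx = mmr_select(qvec, self.vectors[order], stage, self.mmr_lambda)
        dense_ids = [self.ids[order[i]] for i in mmr_idx]
        # stage 2: BM25 union
        bm25_all = self.bm25.scores(tokenize(question))
        lex_ids = sorted(bm25_all, key=lambda c: (-bm25_all[c], c))[:stage]
        union = sorted(set(dense_ids) | set(lex_ids))
        dn = minmax_normalize([float(sims[self.ids.index(c)]) for c in union])
        bn = minmax_normalize([bm25_all[c] for c in union])
        fused = {c: self.alpha * d + (1.0 - self.alpha) * b for c, d, b in zip(union, dn, bn)}
        top = sorted(union, key=lambda c: (-fused[c], c))[: self.k]
        return [(c, self.texts[c]) for c in top]


# ---------------------------------------------------------------------------
# groundedness
# ---------------------------------------------------------------------------


@dataclass
class GroundednessItem:
    context_precision: float
    context_recall: float
    faithfulness: float

    @property
    def hallucination_rate(self) -> float:
        return 1.0 - self.faithfulness


def groundedness(
    answer: str,
    gold_passage: str,
    retrieved: list[str],
    tau_support: float = 0.35,
    match_threshold: float = 0.85,
) -> GroundednessItem:
    """Three fuzzy-Jaccard groundedness metrics for one item.

    A retrieved chunk *supports* the gold passage when their fuzzy Jaccard
    reaches ``tau_support``; a sentence is *supported/retrieved* when its
    best fuzzy Jaccard against any chunk (or, for sentence-grain claims,
    any chunk sentence) reaches ``tau_support``.
    """
    if not answer.strip() or not gold_passage.strip() or not retrieved:
        raise ValueError("answer, gold passage and retrieved chunks must be non-empty")
    chunk_tokens = [tokenize(c).unique for c in retrieved]
    units = list(chunk_tokens)
    for c in retrieved:
        units.extend(tokenize(s).unique for s in split_sentences(c))
    gold_tokens = tokenize(gold_passage)

    supported_chunks = sum(
        1 for ct in chunk_tokens if fuzzy_jaccard(ct, gold_tokens, match_threshold) >= tau_support
    )
    context_precision = supported_chunks / len(retrieved)

    gold_sents = list(split_sentences(gold_passage))
    recalled = sum(
        1
        for s in gold_sents
        if max(fuzzy_jaccard(tokenize(s), u, match_threshold) for u in units) >= tau_support
    )
    context_recall = recalled / len(gold_sents)

    ans_sents = list(split_sentences(answer))
    faithful = sum(
        1
        for s in ans_sents
        if max(fuzzy_jaccard(tokenize(s), u, match_threshold) for u in units) >= tau_support
    )
    faithfulness = faithful / len(ans_sents)
    return GroundednessItem(context_precision, context_recall, faithfulness)


@dataclass
class GroundednessReport:
    context_precision: float
    context_recall: float
    faithfulness: float
    hallucination_rate: float
    items: list[GroundednessItem]


def groundedness_batch(items: list[GroundednessItem]) -> GroundednessReport:
    if not items:
        raise ValueError("no items")
    cp = float(np.mean([i.context_precision for i in items]))
    cr = float(np.mean([i.context_recall for i in items]))
    f = float(np.mean([i.faithfulness for i in items]))
    return GroundednessReport(cp, cr, f, 1.0 - f, items)


# ---------------------------------------------------------------------------
# fluency
# ---------------------------------------------------------------------------


def _ngrams(tokens: tuple[str, ...], n: int) -> Counter:
    return Counter(tokens[i : i + n] for i in range(len(tokens) - n + 1))


def bleu(candidate: str, reference: str, max_order: int = 4) -> float:
    """Corpus-of-one BLEU with uniform weights and brevity penalty.

    Orders above the candidate length are skipped; a zero higher-order
    precision is add-one smoothed, but zero unigram overlap scores 0.
    """
    cand = tokenize(candidate).tokens
    ref = tokenize(reference).tokens
    if not cand or not ref:
        return 0.0
    orders = min(max_order, len(cand))
    log_sum = 0.0
    for n in range(1, orders + 1):
        c_ngrams = _ngrams(cand, n)
        r_ngrams = _ngrams(ref, n)
        total = sum(c_ngrams.values())
        clipped = sum(min(c, r_ngrams[g]) for g, c in c_ngrams.items())
        if n == 1 and clipped == 0:
            return 0.0
        if clipped == 0:
            clipped, total = clipped + 1, total + 1  # add-one smoothing
        log_sum += math.log(clipped / total)
    geo = math.exp(log_sum / orders)
    bp = 1.0 if len(cand) > len(ref) else math.exp(1.0 - len(ref) / len(cand))
    return bp * geo


def rouge_n(candidate: str, reference: str, n: int) -> float:
    """ROUGE-n F1: clipped n-gram overlap."""
    c_ngrams = _ngrams(tokenize(candidate).tokens, n)
    r_ngrams = _ngrams(tokenize(reference).tokens, n)
    overlap = sum(min(c, r_ngrams[g]) for g, c in c_ngrams.items())
    c_total = sum(c_ngrams.values())
    r_total = sum(r_ngrams.values())
    if overlap == 0 or c_total == 0 or r_total == 0:
        return 0.0
    p = overlap / c_total
    r = overlap / r_total
    return 2 * p * r / (p + r)


def _lcs_length(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    if len(a) < len(b):
        a, b = b, a
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if ca == cb else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def rouge_l(candidate: str, reference: str) -> float:
    """ROUGE-L F1 from the longest common token subsequence."""
    cand = tokenize(candidate).tokens
    ref = tokenize(reference).tokens
    if not cand or not ref:
        return 0.0
    lcs = _lcs_length(cand, ref)
    if lcs == 0:
        return 0.0
    p = lcs / len(cand)
    r = lcs / len(ref)
    return 2 * p * r / (p + r)


def embedding_f1(
    candidate: str, reference: str, backend: HashedEmbeddingBackend
) -> float:
    """Greedy token-embedding matching F1 (BERTScore-style, hash analogue)."""
    cand = tokenize(candidate).tokens
    ref = tokenize(reference).tokens
    if not cand or not ref:
        return 0.0
    c_vecs = np.array([backend.token_vector(t) for t in cand])
    r_vecs = np.array([backend.token_vector(t) for t in ref])
    sims = c_vecs @ r_vecs.T
    precision = float(sims.max(axis=1).mean())
    recall = float(sims.max(axis=0).mean())
    if precision + recall <= 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class FluencyItem:
    bleu: float
    rouge1: float
    rouge2: float
    rougeL: float
    bertscore_f1: float  # hash-embedding analogue under the default backend


def fluency(
    candidate: str, reference: str, backend: HashedEmbeddingBackend | None = None
) -> FluencyItem:
    if not candidate.strip() or not reference.strip():
        raise ValueError("candidate and reference must be non-empty")
    backend = backend or HashedEmbeddingBackend()
    return FluencyItem(
        bleu=bleu(candidate, reference),
        rouge1=rouge_n(candidate, reference, 1),
        rouge2=rouge_n(candidate, reference, 2),
        rougeL=rouge_l(candidate, reference),
        bertscore_f1=embedding_f1(candidate, reference, backend),
    )


def fluency_batch(items: list[FluencyItem]) -> dict[str, float]:
    if not items:
        raise ValueError("no items")
    return {
        name: float(np.mean([getattr(i, name) for i in items]))
        for name in ("bleu", "rouge1", "rouge2", "rougeL", "bertscore_f1")
    }


# ---------------------------------------------------------------------------
# readability
# ---------------------------------------------------------------------------

_VOWELS = set("aeiouy")
_SYLLABLE_EXCEPTIONS = {
    "area": 3, "being": 2, "quiet": 2, "idea": 3, "real": 1, "really": 2,
    "science": 2, "create": 2, "created": 3,
}


def count_syllables(word: str) -> int:
    """Deterministic rule-based syllable count: vowel groups, with a silent
    final 'e' (kept for consonant+'le') and a small exception table."""
    w = "".join(ch for ch in word.lower() if ch.isalpha())
    if not w:
        return 0
    if w in _SYLLABLE_EXCEPTIONS:
        return _SYLLABLE_EXCEPTIONS[w]
    groups = 0
    prev_vowel = False
    for ch in w:
        is_vowel = ch in _VOWELS
        if is_vowel and not prev_vowel:
            groups += 1
        prev_vowel = is_vowel
    if w.endswith("e") and not w.endswith(("le", "ee", "ye", "oe", "ie")) and groups > 1:
        groups -= 1
    return max(groups, 1)


LEVEL_BINS = ("high_school_or_below", "college", "college_graduate")


def reading_level_bin(fk_grade: float) -> str:
    if fk_grade <= 12.0:
        return "high_school_or_below"
    if fk_grade <= 16.0:
        return "college"
    return "college_graduate"


@dataclass
class ReadabilityReport:
    word_count: int
    sentence_count: int
    words_per_sentence: float
    chars_per_word: float
    syllables_per_word: float
    lexical_diversity: float
    punctuation_ratio: float
    fk_grade: float
    flesch_reading_ease: float
    level_bin: str


def readability(text: str) -> ReadabilityReport:
    """Language-structure and readability profile of one text.

    ``FKGL = 0.39 (words/sentences) + 11.8 (syllables/words) - 15.59``
    ``FRE  = 206.835 - 1.015 (words/sentences) - 84.6 (syllables/words)``
    """
    tokens = tokenize(text)
    sentences = split_sentences(text)
    if len(tokens) == 0 or len(sentences) == 0:
        raise ValueError("text must contain at least one word and sentence")
    words = len(tokens)
    sents = len(sentences)
    syllables = sum(count_syllables(t) for t in tokens)
    wps = words / sents
    spw = syllables / words
    punct = sum(1 for ch in text if ch in ".,;:!?\"'()[]-—–")
    fkgl = 0.39 * wps + 11.8 * spw - 15.59
    fre = 206.835 - 1.015 * wps - 84.6 * spw
    return ReadabilityReport(
        word_count=words,
        sentence_count=sents,
        words_per_sentence=wps,
        chars_per_word=sum(len(t) for t in tokens) / words,
        syllables_per_word=spw,
        lexical_diversity=len(set(tokens.tokens)) / words,
        punctuation_ratio=punct / max(len(text), 1),
        fk_grade=fkgl,
        flesch_reading_ease=fre,
        level_bin=reading_level_bin(fkgl),
    )


def readability_batch(reports: list[ReadabilityReport]) -> dict:
    if not reports:
        raise ValueError("no reports")
    dist = {b: 0 for b in LEVEL_BINS}
    for r in reports:
        dist[r.level_bin] += 1
    n = len(reports)
    return {
        "mean_fk_grade": float(np.mean([r.fk_grade for r in reports])),
        "mean_flesch_reading_ease": float(np.mean([r.flesch_reading_ease for r in reports])),
        "mean_words": float(np.mean([r.word_count for r in reports])),
        "mean_sentences": float(np.mean([r.sentence_count for r in reports])),
        "level_distribution": {b: dist[b] / n for b in LEVEL_BINS},
    }
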