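"""Groundedness retriever + metrics, fluency metrics, readability."""

import numpy as np
import pytest

from postopqa.index_retrieval import HashedEmbeddingBackend
from postopqa.kb_ingest import SourceDocument
from postopqa.quality_metrics import (
    EvalRetriever,
    bleu,
    chunk_by_words,
    count_syllables,
    embedding_f1,
    fluency,
    fluency_batch,
    groundedness,
    groundedness_batch,
    mmr_select,
    readability,
    readability_batch,
    reading_level_bin,
    rouge_l,
    rouge_n,
)
from postopqa.textcore import fuzzy_jaccard, split_sentences, tokenize

# ---------------------------------------------------------------------------
# evaluation retriever and MMR
# ---------------------------------------------------------------------------


def unit_rows(x):
    x = np.asarray(x, dtype=float)
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def test_mmr_lambda_one_is_pure_similarity_order():
    vecs = unit_rows([[1, 0, 0], [0.9, 0.1, 0], [0, 1, 0], [0, 0, 1]])
    q = np.array([1.0, 0.0, 0.0])
    order = mmr_select(q, vecs, k=4, lam=1.0)
    sims = vecs @ q
    assert order == list(np.argsort(-sims, kind="stable"))


def test_mmr_demotes_duplicates():
    vecs = unit_rows([[1, 0, 0], [1, 0, 0], [0.8, 0.6, 0]])
    q = np.array([1.0, 0.3, 0.0])
    q /= np.linalg.norm(q)
    order = mmr_select(q, vecs, k=3, lam=0.5)
    # the duplicate of the first pick drops below the distinct chunk
    assert order[0] == 0 and order[1] == 2 and order[2] == 1


def test_mmr_matches_independent_reimplementation():
    rng = np.random.default_rng(0)
    vecs = unit_rows(rng.standard_normal((5, 8)))
    q = rng.standard_normal(8)
    q /= np.linalg.norm(q)
    lam = 0.6
    # independent greedy oracle, written directly from the definition
    sims = vecs @ q
    remaining = list(range(5))
    expected = []
    while remaining:
        best, best_score = None, -np.inf
        for i in remaining:
            penalty = max((float(vecs[j] @ vecs[i]) for j in expected), default=0.0)
            score = lam * sims[i] - (0.0 if not expected else (1 - lam) * penalty)
            if score > best_score + 1e-15:
                best, best_score = i, score
        expected.append(best)
        remaining.remove(best)
    assert mmr_select(q, vecs, k=5, lam=lam) == expected


def test_chunk_by_words_respects_sentences_and_budget():
    body = " ".join(["This sentence has exactly six words here."] * 40)
    doc = SourceDocument("d", "t", "t", body)
    chunks = chunk_by_words(doc, chunk_words=50)
    assert len(chunks) > 1
    for _, text in chunks:
        assert len(tokenize(text)) <= 50 + 7  # never splits a sentence
    joined = " ".join(t for _, t in chunks)
    assert joined == body


def test_eval_retriever_finds_topical_chunk(kb_docs):
    retriever = EvalRetriever(kb_docs, k=4)
    got = retriever.retrieve("How often should I empty the drain bulb?")
    assert len(got) == 4
    assert any("drain" in text for _, text in got)


# ---------------------------------------------------------------------------
# groundedness
# ---------------------------------------------------------------------------

CHUNKS = [
    "Keep the incision dry for 48 hours. Shower gently after that.",
    "Change the dressing every morning. Watch the wound edges for warmth.",
    "Short walks help circulation during early recovery.",
]


def test_groundedness_identity_limits():
    item = groundedness(CHUNKS[0], CHUNKS[0], [CHUNKS[0]])
    assert item.context_precision == 1.0
    assert item.context_recall == 1.0
    assert item.faithfulness == 1.0
    assert item.hallucination_rate == 0.0


def test_groundedness_disjoint_answer_has_zero_faithfulness():
    item = groundedness(
        "Quarterly bond yields rallied sharply.", CHUNKS[0], CHUNKS
    )
    assert item.faithfulness == 0.0


def test_groundedness_matches_bruteforce_oracle():
    answer = "Shower gently after that. Stock markets closed early today."
    gold = CHUNKS[0]
    item = groundedness(answer, gold, CHUNKS, tau_support=0.35)
    # oracle: exhaustive sentence x unit scoring
    units = [tokenize(c).unique for c in CHUNKS]
    for c in CHUNKS:
        units.extend(tokenize(s).unique for s in split_sentences(c))
    gold_sents = list(split_sentences(gold))
    recall = np.mean(
        [
            max(fuzzy_jaccard(tokenize(s), u, 0.85) for u in units) >= 0.35
            for s in gold_sents
        ]
    )
    faith = np.mean(
        [
            max(fuzzy_jaccard(tokenize(s), u, 0.85) for u in units) >= 0.35
            for s in split_sentences(answer)
        ]
    )
    precision = np.mean(
        [fuzzy_jaccard(tokenize(c), tokenize(gold), 0.85) >= 0.35 for c in CHUNKS]
    )
    assert item.context_recall == pytest.approx(recall)
    assert item.faithfulness == pytest.approx(faith)
    assert item.context_precision == pytest.approx(precision)
    assert item.faithfulness == pytest.approx(0.5)


def test_faithfulness_monotone_in_support_threshold():
    answer = "Shower gently after that. Short walks help circulation during early recovery."
    values = [
        groundedness(answer, CHUNKS[0], CHUNKS, tau_support=t).faithfulness
        for t in (0.1, 0.3, 0.5, 0.7, 0.9)
    ]
    assert values == sorted(values, reverse=True)


def test_batch_is_mean_of_items():
    items = [
        groundedness(CHUNKS[0], CHUNKS[0], [CHUNKS[0]]),
        groundedness("Bond yields rallied.", CHUNKS[0], CHUNKS),
    ]
    report = groundedness_batch(items)
    assert report.faithfulness == pytest.approx(
        np.mean([i.faithfulness for i in items])
    )
    assert report.hallucination_rate == pytest.approx(1 - report.faithfulness)


# ---------------------------------------------------------------------------
# fluency
# ---------------------------------------------------------------------------


def test_identity_limits_for_all_fluency_metrics():
    text = "Keep the incision dry for 48 hours."
    item = fluency(text, text)
    assert item.bleu == pytest.approx(1.0)
    assert item.rouge1 == pytest.approx(1.0)
    assert item.rouge2 == pytest.approx(1.0)
    assert item.rougeL == pytest.approx(1.0)
    assert item.bertscore_f1 == pytest.approx(1.0)


def test_disjoint_limits():
    item = fluency("alpha beta gamma", "delta epsilon zeta")
    assert item.bleu == 0.0
    assert item.rouge1 == 0.0
    assert item.rouge2 == 0.0
    assert item.rougeL == 0.0


def test_rouge1_hand_counted():
    # unigrams: overlap 3, |cand|=3, |ref|=4 -> P=1, R=3/4, F1=6/7
    assert rouge_n("the cat sat", "the cat sat down", 1) == pytest.approx(6 / 7)


def test_rouge2_and_rougeL_hand_counted():
    cand, ref = "the cat sat", "the cat sat down"
    # bigrams: overlap 2, totals 2 and 3 -> F1 = 2*(1)*(2/3)/(1+2/3) = 4/5
    assert rouge_n(cand, ref, 2) == pytest.approx(0.8)
    # LCS = 3 -> P=1, R=3/4 -> F1 = 6/7
    assert rouge_l(cand, ref) == pytest.approx(6 / 7)


def test_rougeL_dominates_rouge2_on_random_pairs():
    rng = np.random.default_rng(8)
    vocab = "wound care rest walk fever dressing clinic water hours daily".split()
    for _ in range(200):
        a = " ".join(rng.choice(vocab, size=rng.integers(2, 10)))
        b = " ".join(rng.choice(vocab, size=rng.integers(2, 10)))
        assert rouge_l(a, b) >= rouge_n(a, b, 2) - 1e-12


def test_bleu_brevity_penalty_and_smoothing():
    ref = "keep the incision dry for two full days"
    short = "keep the incision dry"
    assert 0.0 < bleu(short, ref) < 1.0
    # candidate longer than reference: no brevity penalty applied
    assert bleu(ref, ref) == pytest.approx(1.0)


def test_embedding_f1_uses_backend_symmetrically():
    backend = HashedEmbeddingBackend(seed=0)
    a, b = "wound care daily", "daily wound care"
    assert embedding_f1(a, b, backend) == pytest.approx(1.0)
    assert embedding_f1(a, b, backend) == pytest.approx(embedding_f1(b, a, backend))


def test_fluency_batch_aggregation():
    items = [fluency("a b c", "a b c"), fluency("a b c", "x y z")]
    batch = fluency_batch(items)
    assert batch["rouge1"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# readability
# ---------------------------------------------------------------------------


def test_flesch_formulas_on_stated_syllable_counts():
    text = "The cat sat on the mat."
    assert sum(count_syllables(t) for t in tokenize(text)) == 6
    rep = readability(text)
    assert rep.word_count == 6 and rep.sentence_count == 1
    assert rep.flesch_reading_ease == pytest.approx(116.145)
    assert rep.fk_grade == pytest.approx(-1.45)
    assert rep.level_bin == "high_school_or_below"


def test_ratio_invariance_under_self_concatenation():
    text = "Change the dressing every morning. Watch the wound closely."
    doubled = text + " " + text
    r1, r2 = readability(text), readability(doubled)
    assert r1.words_per_sentence == pytest.approx(r2.words_per_sentence)
    assert r1.syllables_per_word == pytest.approx(r2.syllables_per_word)
    assert r1.fk_grade == pytest.approx(r2.fk_grade)


def test_fre_and_fkgl_move_oppositely_with_syllable_load():
    simple = "The cat sat on the mat. The dog ran to the door."
    heavy = (
        "Anesthesiology complications necessitate interdisciplinary rehabilitation. "
        "Physiological recuperation demands considerable perseverance."
    )
    rs, rh = readability(simple), readability(heavy)
    assert rh.syllables_per_word > rs.syllables_per_word
    assert rh.fk_grade > rs.fk_grade
    assert rh.flesch_reading_ease < rs.flesch_reading_ease


def test_level_bins_partition():
    assert reading_level_bin(5.0) == "high_school_or_below"
    assert reading_level_bin(12.0) == "high_school_or_below"
    assert reading_level_bin(14.0) == "college"
    assert reading_level_bin(17.0) == "college_graduate"
    reports = [readability("The cat sat on the mat."), readability("Dogs bark loudly.")]
    dist = readability_batch(reports)["level_distribution"]
    assert sum(dist.values()) == pytest.approx(1.0)


def test_syllable_counter_spot_checks():
    assert count_syllables("dressing") == 2
    assert count_syllables("incision") == 3
    assert count_syllables("care") == 1  # silent final e
    assert count_syllables("gentle") == 2  # consonant + le retains the group
    assert count_syllables("a") == 1


def test_readability_rejects_empty_text():
    with pytest.raises(ValueError):
        readability("   ")
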