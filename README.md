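# postopqa

Grounded retrieval-augmented question answering (RAG) for postoperative
patient education — built desk-scale, provider-agnostic, and fully
deterministic, together with the complete evaluation framework such a
system needs before it can face patients.

## The problem

After surgery, patients and caregivers generate a high volume of
repetitive questions (wound care, showering, pain medication, when to
worry). A conversational assistant can absorb much of that load, but a
free-running language model hallucinates — unacceptable in clinical use.
The standard remedy is retrieval-augmented generation over a curated,
clinician-verified knowledge base, with hard gates between the generator
and the patient:

1. **Ingestion** — patient-handout documents are segmented into ~500
   character, sentence-respecting, non-overlapping chunks, embedded as
   768-dimensional vectors and stored in an HNSW approximate
   nearest-neighbour index (M = 32, efConstruction = 200).
2. **Retrieval** — the 10 chunks nearest the query embedding are re-ranked
   by a hybrid score `alpha * cosine + (1 - alpha) * BM25` (min–max
   normalized within the candidate set); the top 3 form the evidence set.
3. **Generation** — an augmented prompt (fixed role instruction +
   question + evidence) feeds a pluggable generator. The local default is
   a deterministic extractive generator; a hosted LLM drops into the same
   contract.
4. **Gates** — every answer sentence must align with the evidence above a
   grounding threshold (fuzzy-Jaccard, all-sentences rule), and every
   numeral in the answer must occur in the evidence. Failures produce a
   safe handoff message, never silence.
5. **Safety routing** — before any generation, a lexicon-based detector
   escalates red-flag symptom reports (dyspnea, uncontrolled bleeding,
   chest pain, ...) and a two-signal filter (low retrieval affinity AND no
   medical vocabulary) declines non-medical queries.

Because no real corpus of this kind is public, the package ships a
synthetic study-condition factory: a 20-topic knowledge base and a
750-query corpus (200 in-scope + 40 out-of-scope + 10 escalation base
queries, each with two rule-based paraphrases), plus a simulated
three-reviewer rating panel. Everything is generated from a seed, so the
whole stack is testable offline and byte-reproducible.

The evaluation framework covers classification metrics with Wald/Wilson
intervals, topic-level accuracy, majority-vote consensus, inter-rater
reliability (Fleiss' and Cohen's kappa, Krippendorff's alpha,
two-way-random ICC), groundedness (context precision/recall, faithfulness
via a two-stage MMR+BM25 evaluation retriever over 300-word chunks),
fluency (BLEU, ROUGE-1/2/L, an embedding-F1 BERTScore analogue) and
readability (Flesch–Kincaid grade, Flesch reading ease).

## Worked example

```bash
postopqa answer "When can I take a full shower after surgery?" --seed 1
```

or from Python:

```python
from postopqa import app
from postopqa.config import RunConfig

pipeline, _ = app.build_serving_stack(RunConfig(seed=1))
answer = pipeline.answer_query("When can I take a full shower after surgery?", "demo")
print(answer.status)   # delivered
print(answer.text)
```

prints (seed 1):

```
delivered
Most patients can safely take a full shower about 4 days after surgery,
once the surgical team agrees. ...
```

with `answer.sentence_scores == [1.0, 1.0, 1.0, 1.0, 1.0]` (every sentence
is verbatim evidence, so grounding confidence is 1.0) and
`answer.evidence_ids == ['topic11:000', 'topic12:000', 'topic06:000']`
recording the audited evidence chunks. A non-medical query
(`"Which movie won best picture this year?"`) returns `declined_scope`
with a scope-decline template, and a red-flag report
(`"I can't breathe and blood is soaking through the bandage"`) returns
`escalated` with an urgent-care handoff — no generation is attempted.

`postopqa run --out run --seed 1` reproduces the full workflow (fixtures →
ingest → index → 750 answers → human + automated metric reports) into a
run directory keyed by the config hash.

## Layout

| module | role |
| --- | --- |
| `textcore` | tokenizer, sentence splitter, fuzzy Jaccard |
| `kb_ingest` | document loading, ~500-char sentence-packing chunker |
| `hnsw`, `index_retrieval` | embeddings, HNSW index, BM25, hybrid retrieval |
| `answer_pipeline` | prompt, extractive generator, grounding + numeral gates |
| `safety_router` | escalation and out-of-scope routing |
| `eval_stats` | consensus, classification metrics, reliability suite |
| `quality_metrics` | groundedness, fluency, readability batteries |
| `corpus_factory` | synthetic KB / corpus / ratings generator |
| `app`, `config` | orchestration, run config, CLI |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
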