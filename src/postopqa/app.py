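"""End-to-end orchestration and the command-line interface.

``run_pipeline`` reproduces a complete study run from one config:
fixtures -> ingest -> index -> route+answer the 750-query corpus ->
human-evaluation metrics (router confusion matrix, topic accuracy,
simulated-panel reliability) -> automated metrics (fluency, readability,
groundedness).  Every output directory carries the config and its hash so
deterministic stages are bit-reproducible.

The CLI is a thin typer layer over the library: ``postopqa run`` for the
whole pipeline, plus per-stage subcommands.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import typer

from . import corpus_factory, eval_stats, quality_metrics
from .answer_pipeline import AnswerPipeline, VerifiedAnswer
from .config import RunConfig
from .index_retrieval import VectorIndex
from .kb_ingest import chunk_document, load_documents, write_chunks_jsonl


def build_serving_stack(config: RunConfig) -> tuple[AnswerPipeline, list]:
    """Generate the KB, chunk it, build the index and the pipeline."""
    docs = corpus_factory.generate_kb(config.seed)
    chunks = [
        c
        for doc in docs
        for c in chunk_document(doc, config.chunk_limit, config.paragraph_breaks)
    ]
    index = VectorIndex(chunks, config=config.index)
    return AnswerPipeline(index, config.pipeline), docs


def answer_corpus(
    pipeline: AnswerPipeline, records: list[corpus_factory.QueryRecord]
) -> list[VerifiedAnswer]:
    return [pipeline.answer_query(r.text, r.query_id) for r in records]


def routing_confusion(
    records: list[corpus_factory.QueryRecord], answers: list[VerifiedAnswer]
) -> eval_stats.ConfusionMatrix:
    """Router/pipeline confusion matrix: in-scope queries are the positive
    class (predicted positive = an answer was attempted)."""
    tp = fp = fn = tn = 0
    for rec, ans in zip(records, answers):
        predicted_positive = ans.status in (
            "delivered", "rejected_grounding", "rejected_heuristic", "fallback_handoff",
        )
        if rec.category == "in_scope":
            tp += predicted_positive
            fn += not predicted_positive
        else:
            fp += predicted_positive
            tn += not predicted_positive
    return eval_stats.ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def human_metrics(
    records: list[corpus_factory.QueryRecord],
    answers: list[VerifiedAnswer],
    ratings: list[eval_stats.RatingRecord],
) -> dict:
    cm = routing_confusion(records, answers)
    per_topic: dict[str, list[int]] = {}
    for rec, ans in zip(records, answers):
        topic = rec.topic or f"({rec.category})"
        ok = (
            ans.status not in ("declined_scope", "escalated")
            if rec.category == "in_scope"
            else ans.status in ("declined_scope", "escalated")
        )
        per_topic.setdefault(topic, []).append(int(ok))
    topic_table = {t: (sum(v), len(v)) for t, v in per_topic.items()}

    by_query: dict[str, list[int]] = {}
    for r in ratings:
        by_query.setdefault(r.query_id, []).append(r.correct)
    qids = sorted(by_query)
    reviewer_ids = sorted({r.reviewer_id for r in ratings})
    label_matrix = np.array(
        [
            [next(x.correct for x in ratings if x.query_id == q and x.reviewer_id == rid) for q in qids]
            for rid in reviewer_ids
        ]
    )
    completeness = np.array(
        [
            [next(x.completeness for x in ratings if x.query_id == q and x.reviewer_id == rid) for rid in reviewer_ids]
            for q in qids
        ]
    )
    rel = eval_stats.reliability_report(label_matrix, completeness)
    return {
        "confusion_matrix": asdict(cm),
        "classification": eval_stats.classification_metrics(cm),
        "topic_accuracy": eval_stats.topic_accuracy(topic_table),
        "consensus_correct_rate": float(
            np.mean(list(eval_stats.consensus(by_query).values()))
        ),
        "likert": {
            f: eval_stats.likert_summary(ratings, f)
            for f in ("completeness", "consistency", "ssi")
        },
        "reliability": {
            "fleiss_kappa": rel.fleiss_kappa.value,
            "pairwise_cohen_mean": rel.pairwise_cohen["mean"],
            "krippendorff_nominal": rel.krippendorff_nominal.value,
            "krippendorff_ordinal": rel.krippendorff_ordinal.value,
            "icc_2_1": rel.icc_2_1.value,
            "icc_2_k": rel.icc_2_k.value,
        },
    }


def auto_metrics(
    records: list[corpus_factory.QueryRecord],
    answers: list[VerifiedAnswer],
    docs: list,
    config: RunConfig,
    max_groundedness_items: int | None = None,
) -> dict:
    delivered = [
        (rec, ans)
        for rec, ans in zip(records, answers)
        if ans.status == "delivered" and rec.gold_reference
    ]
    if not delivered:
        return {"n_delivered": 0}
    fluency_items = [
        quality_metrics.fluency(ans.text, rec.gold_reference) for rec, ans in delivered
    ]
    readability_items = [quality_metrics.readability(ans.text) for _, ans in delivered]
    retriever = quality_metrics.EvalRetriever(
        docs,
        chunk_words=config.evaluation.eval_chunk_words,
        k=config.evaluation.eval_k,
        mmr_lambda=config.evaluation.mmr_lambda,
    )
    subset = delivered[:max_groundedness_items] if max_groundedness_items else delivered
    ground_items = []
    for rec, ans in subset:
        retrieved = [text for _, text in retriever.retrieve(rec.text)]
        ground_items.append(
            quality_metrics.groundedness(
                ans.text, rec.gold_passage, retrieved, config.evaluation.tau_support
            )
        )
    ground = quality_metrics.groundedness_batch(ground_items)
    return {
        "n_delivered": len(delivered),
        "fluency": quality_metrics.fluency_batch(fluency_items),
        "readability": quality_metrics.readability_batch(readability_items),
        "groundedness": {
            "context_precision": ground.context_precision,
            "context_recall": ground.context_recall,
            "faithfulness": ground.faithfulness,
            "hallucination_rate": ground.hallucination_rate,
            "n_items": len(ground_items),
        },
    }


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    max_groundedness_items: int | None = None,
) -> dict:
    """Execute the full workflow and write all artefacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")

    docs = corpus_factory.generate_kb(config.seed)
    corpus_factory.write_kb(docs, out / "kb")
    records = corpus_factory.generate_corpus(config.seed)
    corpus_factory.write_corpus_jsonl(records, out / "corpus.jsonl")
    base_ids = sorted({r.base_id for r in records})
    ratings = corpus_factory.simulate_ratings(base_ids, seed=config.seed)
    corpus_factory.write_ratings_jsonl(ratings, out / "ratings.jsonl")

    chunks = [
        c for d in docs for c in chunk_document(d, config.chunk_limit, config.paragraph_breaks)
    ]
    write_chunks_jsonl(chunks, out / "chunks.jsonl")
    index = VectorIndex(chunks, config=config.index)
    pipeline = AnswerPipeline(index, config.pipeline)

    answers = answer_corpus(pipeline, records)
    (out / "answers.jsonl").write_text(
        "\n".join(a.to_json() for a in answers) + "\n", encoding="utf-8"
    )

    summary = {
        "config_hash": config.config_hash(),
        "n_queries": len(records),
        "status_counts": _status_counts(answers),
        "human_metrics": human_metrics(records, answers, ratings),
        "auto_metrics": auto_metrics(records, answers, docs, config, max_groundedness_items),
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str), encoding="utf-8"
    )
    return summary


def _status_counts(answers: list[VerifiedAnswer]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a in answers:
        counts[a.status] = counts.get(a.status, 0) + 1
    return dict(sorted(counts.items()))


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

cli = typer.Typer(help="Grounded postoperative patient-education QA toolkit.")


@cli.command("make-fixtures")
def cli_make_fixtures(out: Path = Path("fixtures"), seed: int = 0) -> None:
    """Generate the synthetic knowledge base, query corpus and ratings."""
    docs = corpus_factory.generate_kb(seed)
    corpus_factory.write_kb(docs, out / "kb")
    records = corpus_factory.generate_corpus(seed)
    corpus_factory.write_corpus_jsonl(records, out / "corpus.jsonl")
    ratings = corpus_factory.simulate_ratings(sorted({r.base_id for r in records}), seed=seed)
    corpus_factory.write_ratings_jsonl(ratings, out / "ratings.jsonl")
    typer.echo(f"wrote {len(docs)} documents, {len(records)} queries to {out}")


@cli.command("ingest")
def cli_ingest(kb_dir: Path, out: Path = Path("chunks.jsonl"), chunk_limit: int = 500) -> None:
    """Chunk a directory of knowledge-base documents."""
    docs = load_documents(kb_dir)
    chunks = [c for d in docs for c in chunk_document(d, chunk_limit)]
    write_chunks_jsonl(chunks, out)
    typer.echo(f"wrote {len(chunks)} chunks from {len(docs)} documents to {out}")


@cli.command("answer")
def cli_answer(question: str, seed: int = 0) -> None:
    """Answer a single question against the synthetic knowledge base."""
    pipeline, _ = build_serving_stack(RunConfig(seed=seed))
    ans = pipeline.answer_query(question, "cli")
    typer.echo(ans.to_json())


@cli.command("batch")
def cli_batch(corpus: Path, out: Path = Path("answers.jsonl"), seed: int = 0) -> None:
    """Answer every query in a JSONL corpus."""
    records = corpus_factory.read_corpus_jsonl(corpus)
    pipeline, _ = build_serving_stack(RunConfig(seed=seed))
    answers = answer_corpus(pipeline, records)
    out.write_text("\n".join(a.to_json() for a in answers) + "\n", encoding="utf-8")
    typer.echo(json.dumps(_status_counts(answers)))


@cli.command("evaluate-human")
def cli_evaluate_human(out: Path = Path("human_metrics.json"), seed: int = 0) -> None:
    """Routing confusion matrix, topic accuracy and reliability suite."""
    config = RunConfig(seed=seed)
    pipeline, _ = build_serving_stack(config)
    records = corpus_factory.generate_corpus(seed)
    answers = answer_corpus(pipeline, records)
    ratings = corpus_factory.simulate_ratings(sorted({r.base_id for r in records}), seed=seed)
    metrics = human_metrics(records, answers, ratings)
    out.write_text(json.dumps(metrics, indent=2, sort_keys=True, default=str), encoding="utf-8")
    typer.echo(f"accuracy {metrics['classification']['accuracy']:.4f} -> {out}")


@cli.command("evaluate-auto")
def cli_evaluate_auto(
    out: Path = Path("auto_metrics.json"), seed: int = 0, limit: int = 100
) -> None:
    """Fluency, readability and groundedness battery on delivered answers."""
    config = RunConfig(seed=seed)
    pipeline, docs = build_serving_stack(config)
    records = corpus_factory.generate_corpus(seed)
    answers = answer_corpus(pipeline, records)
    metrics = auto_metrics(records, answers, docs, config, max_groundedness_items=limit)
    out.write_text(json.dumps(metrics, indent=2, sort_keys=True, default=str), encoding="utf-8")
    typer.echo(f"evaluated {metrics['n_delivered']} delivered answers -> {out}")


@cli.command("run")
def cli_run(out: Path = Path("run"), seed: int = 0, limit: int = 100) -> None:
    """Full reproduction: fixtures -> ingest -> index -> answer -> evaluate."""
    summary = run_pipeline(RunConfig(seed=seed), out, max_groundedness_items=limit)
    typer.echo(json.dumps(summary["status_counts"]))


def main() -> None:  # console-script entry point
    cli()
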