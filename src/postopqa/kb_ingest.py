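"""Knowledge-base ingestion: load patient-education documents and segment
them into ~500-character, sentence-respecting, non-overlapping chunks.

The chunk is the retrieval unit.  "Semantic coherence" is operationalized
as never splitting a sentence and (optionally) forcing a chunk boundary at
paragraph breaks once a chunk is mostly full; an oversize sentence is kept
whole and flagged rather than split, preserving the grounding unit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .textcore import split_sentences, tokenize

DEFAULT_CHUNK_LIMIT = 500
PARAGRAPH_BREAK_FILL = 0.6  # force a boundary at a paragraph break when this full


@dataclass(frozen=True)
class SourceDocument:
    doc_id: str
    topic: str
    title: str
    body: str

    def __post_init__(self) -> None:
        if not self.body.strip():
            raise ValueError(f"document {self.doc_id!r} has an empty body")


@dataclass(frozen=True)
class Chunk:
    chunk_id: str
    doc_id: str
    topic: str
    text: str
    char_span: tuple[int, int]
    token_count: int
    overflow: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "chunk_id": self.chunk_id,
                "doc_id": self.doc_id,
                "topic": self.topic,
                "text": self.text,
                "char_span": list(self.char_span),
                "token_count": self.token_count,
                "overflow": self.overflow,
            }
        )


_MD_HEADER = ("#", "##", "###", "####")


def _parse_file(path: Path) -> tuple[str, str, str]:
    """Return (topic, title, body) for one text/Markdown file."""
    raw = path.read_text(encoding="utf-8")
    topic = "unassigned"
    title = path.stem
    body_lines: list[str] = []
    for line in raw.splitlines():
        stripped = line.strip()
        low = stripped.lower()
        if low.startswith("topic:"):
            topic = stripped.split(":", 1)[1].strip() or "unassigned"
            continue
        if stripped.startswith(_MD_HEADER):
            header = stripped.lstrip("#").strip()
            if header and title == path.stem:
                title = header
            continue
        body_lines.append(line)
    return topic, title, "\n".join(body_lines).strip()


def load_documents(path: str | Path) -> list[SourceDocument]:
    """Load every ``.txt``/``.md`` file under ``path`` (file or directory).

    An optional ``topic:`` header line assigns the document's topic
    (default ``"unassigned"``); Markdown headers are stripped from the body.
    Empty files are skipped with a warning; unreadable files raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    files = [path] if path.is_file() else sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".txt", ".md"}
    )
    docs: list[SourceDocument] = []
    for f in files:
        try:
            topic, title, body = _parse_file(f)
        except OSError as exc:
            raise OSError(f"cannot read knowledge-base file {f}: {exc}") from exc
        if not body:
            warnings.warn(f"skipping empty knowledge-base file {f}", stacklevel=2)
            continue
        docs.append(SourceDocument(doc_id=f.stem, topic=topic, title=title, body=body))
    if not docs:
        warnings.warn(f"no knowledge-base documents found under {path}", stacklevel=2)
    return docs


def _paragraph_spans(body: str) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    pos = 0
    for para in body.split("\n\n"):
        spans.append((pos, pos + len(para)))
        pos += len(para) + 2
    return spans


def chunk_document(
    doc: SourceDocument,
    chunk_limit: int = DEFAULT_CHUNK_LIMIT,
    paragraph_breaks: bool = True,
) -> list[Chunk]:
    """Greedy sentence-packing into non-overlapping chunks.

    Sentences are appended while the chunk span stays within ``chunk_limit``
    characters; a single longer sentence becomes its own chunk flagged
    ``overflow``.  With ``paragraph_breaks``, a paragraph boundary closes the
    current chunk once it is at least 60% full.  Chunk spans are pairwise
    disjoint and in document order, and every sentence lands in exactly one
    chunk.
    """
    if chunk_limit < 100:
        raise ValueError("chunk_limit must be >= 100")
    body = doc.body
    # sentences annotated with their paragraph index
    units: list[tuple[int, int, int]] = []  # (start, end, paragraph)
    for p_idx, (p_start, p_end) in enumerate(_paragraph_spans(body)):
        para = body[p_start:p_end]
        for s, e in split_sentences(para).spans:
            units.append((p_start + s, p_start + e, p_idx))
    if not units:
        raise ValueError(f"document {doc.doc_id!r} contains no sentences")

    chunks: list[Chunk] = []
    cur_start, cur_end, cur_para = units[0][0], units[0][1], units[0][2]

    def flush() -> None:
        text = body[cur_start:cur_end]
        chunks.append(
            Chunk(
                chunk_id=f"{doc.doc_id}:{len(chunks):03d}",
                doc_id=doc.doc_id,
                topic=doc.topic,
                text=text,
                char_span=(cur_start, cur_end),
                token_count=len(tokenize(text)),
                overflow=len(text) > chunk_limit,
            )
        )

    for s, e, p in units[1:]:
        new_para = paragraph_breaks and p != cur_para
        fill = cur_end - cur_start
        if (e - cur_start > chunk_limit) or (new_para and fill >= PARAGRAPH_BREAK_FILL * chunk_limit):
            flush()
            cur_start, cur_end = s, e
        else:
            cur_end = e
        cur_para = p
    flush()
    return chunks


def write_chunks_jsonl(chunks: list[Chunk], path: str | Path) -> None:
    Path(path).write_text("\n".join(c.to_json() for c in chunks) + "\n", encoding="utf-8")


def read_chunks_jsonl(path: str | Path) -> list[Chunk]:
    chunks = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        chunks.append(
            Chunk(
                chunk_id=d["chunk_id"],
                doc_id=d["doc_id"],
                topic=d["topic"],
                text=d["text"],
                char_span=tuple(d["char_span"]),
                token_count=d["token_count"],
                overflow=d.get("overflow", False),
            )
        )
    return chunks
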