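"""Embedding contract, vector index and the hybrid retrieval path.

The serving pipeline retrieves the ten passages most similar to the query
embedding from an HNSW index (M=32, efConstruction=200 defaults), re-ranks
those candidates by a convex combination of min-max-normalized dense cosine
and Okapi BM25 scores, and returns the top three as the evidence set, with
the full top-10 trace retained for auditing.

The default embedding backend is a seeded token-hash superposition: each
vocabulary token maps through a keyed hash to a fixed pseudo-random unit
vector, and a text embeds as the L2-normalized sum of its (stopword-
filtered) token vectors weighted by sublinear term frequency ``1 + log tf``.
It is deterministic, needs no downloads, and any external embedding service
can be plugged in behind the same ``embed(text) -> vector`` contract.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .hnsw import HNSWIndex
from .kb_ingest import Chunk
from .textcore import TokenSequence, tokenize

DEFAULT_DIMENSION = 768

# function words excluded from dense embeddings so that shared syntax alone
# does not create affinity between unrelated texts
STOPWORDS = frozenset(
    """a an the and or but if then than so of to in on at by for with from as is
    are was were be been being am do does did have has had will would can could
    may might shall should must it its this that these those i you he she we
    they me him her us them my your his our their what which who whom when
    where why how not no nor there here also very just about into over under
    again once only own same too s t don now
    after before while until any some all each every much many most more less
    few first last next new old long short full best good well right way early
    still yet ever never always often sometimes usually typically
    get gets got keep keeps kept make makes made need needs needed want wants
    take takes took go goes going gone come comes start starts started stop
    stops stopped check checks checked look looks looked""".split()
)


@dataclass
class IndexConfig:
    M: int = 32
    ef_construction: int = 200
    ef_search: int = 100
    dimension: int = DEFAULT_DIMENSION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.ef_construction < self.M:
            raise ValueError("ef_construction must be >= M")


class HashedEmbeddingBackend:
    """Deterministic hashed-bag embedding backend (the local default)."""

    def __init__(
        self,
        dimension: int = DEFAULT_DIMENSION,
        seed: int = 0,
        drop_stopwords: bool = True,
    ) -> None:
        self.dimension = dimension
        self.seed = seed
        self.drop_stopwords = drop_stopwords
        self._cache: dict[str, np.ndarray] = {}

    def token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                token.encode("utf-8"), digest_size=8, key=str(self.seed).encode()
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            vec = rng.standard_normal(self.dimension)
            vec /= np.linalg.norm(vec)
            self._cache[token] = vec
        return vec

    def embed(self, text: str) -> np.ndarray:
        """Embed ``text``; the zero vector signals a zero-information input."""
        tokens = [t for t in tokenize(text)]
        if self.drop_stopwords:
            tokens = [t for t in tokens if t not in STOPWORDS]
        if not tokens:
            return np.zeros(self.dimension)
        counts: dict[str, int] = {}
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
        vec = np.zeros(self.dimension)
        for t, c in counts.items():
            vec += (1.0 + math.log(c)) * self.token_vector(t)
        norm = np.linalg.norm(vec)
        if norm == 0:  # pragma: no cover - astronomically unlikely
            return np.zeros(self.dimension)
        return vec / norm


def is_degenerate(vec: np.ndarray) -> bool:
    return not np.any(vec)


class BM25Corpus:
    """Okapi BM25 statistics over a chunk corpus.

    ``score(q, d) = sum_t IDF(t) * f(t,d)(k1+1) / (f(t,d) + k1(1-b+b|d|/avgdl))``
    with ``IDF(t) = ln((N-df+0.5)/(df+0.5) + 1)``; scores are non-negative.
    """

    def __init__(self, tokens_by_id: dict[str, TokenSequence], k1: float = 1.5, b: float = 0.75):
        if not tokens_by_id:
            raise ValueError("empty corpus")
        self.k1 = k1
        self.b = b
        self._tf: dict[str, dict[str, int]] = {}
        self._len: dict[str, int] = {}
        df: dict[str, int] = {}
        for cid, toks in tokens_by_id.items():
            counts: dict[str, int] = {}
            for t in toks:
                counts[t] = counts.get(t, 0) + 1
            self._tf[cid] = counts
            self._len[cid] = len(toks)
            for t in counts:
                df[t] = df.get(t, 0) + 1
        self.N = len(tokens_by_id)
        self.avgdl = sum(self._len.values()) / self.N
        self._idf = {
            t: math.log((self.N - d + 0.5) / (d + 0.5) + 1.0) for t, d in df.items()
        }

    def scores(
        self, query: TokenSequence, candidate_ids: list[str] | None = None
    ) -> dict[str, float]:
        ids = candidate_ids if candidate_ids is not None else list(self._tf)
        out: dict[str, float] = {}
        for cid in ids:
            tf = self._tf[cid]
            dl = self._len[cid]
            norm = self.k1 * (1.0 - self.b + self.b * dl / self.avgdl)
            s = 0.0
            for t in query:
                f = tf.get(t, 0)
                if f:
                    s += self._idf.get(t, 0.0) * f * (self.k1 + 1.0) / (f + norm)
            out[cid] = s
        return out


@dataclass(frozen=True)
class ScoredCandidate:
    chunk_id: str
    dense_score: float
    bm25_score: float = 0.0
    fused_score: float | None = None


@dataclass
class EvidenceSet:
    query_id: str
    candidates: list[ScoredCandidate]
    retrieval_trace: list[ScoredCandidate] = field(default_factory=list)
    short_corpus: bool = False
    degenerate_query: bool = False

    @property
    def chunk_ids(self) -> list[str]:
        return [c.chunk_id for c in self.candidates]


class VectorIndex:
    """HNSW index plus corpus lexical statistics over a fixed chunk set."""

    def __init__(
        self,
        chunks: list[Chunk],
        config: IndexConfig | None = None,
        backend: HashedEmbeddingBackend | None = None,
        k1: float = 1.5,
        b: float = 0.75,
    ) -> None:
        if not chunks:
            raise ValueError("cannot build an index over zero chunks")
        self.config = config or IndexConfig()
        self.backend = backend or HashedEmbeddingBackend(self.config.dimension, self.config.seed)
        if self.backend.dimension != self.config.dimension:
            raise ValueError("embedding backend dimension does not match index config")
        # insertion order fixed by chunk_id sort for reproducibility
        self.chunks: dict[str, Chunk] = {c.chunk_id: c for c in sorted(chunks, key=lambda c: c.chunk_id)}
        if len(self.chunks) != len(chunks):
            raise ValueError("duplicate chunk_id in corpus")
        self._tokens = {cid: tokenize(c.text) for cid, c in self.chunks.items()}
        self.bm25 = BM25Corpus(self._tokens, k1=k1, b=b)
        self.hnsw = HNSWIndex(
            dim=self.config.dimension,
            M=self.config.M,
            ef_construction=self.config.ef_construction,
            ef_search=self.config.ef_search,
            seed=self.config.seed,
        )
        ids = list(self.chunks)
        vecs = np.array([self.backend.embed(self.chunks[cid].text) for cid in ids])
        keep = [i for i in range(len(ids)) if np.any(vecs[i])]
        if not keep:
            raise ValueError("no chunk produced a non-degenerate embedding")
        self.hnsw.add_items(vecs[keep], [ids[i] for i in keep])

    def __len__(self) -> int:
        return len(self.chunks)

    def dense_top(self, query_vec: np.ndarray, k: int) -> tuple[list[str], list[float]]:
        return self.hnsw.knn_query(query_vec, k)

    def best_dense_score(self, query_text: str) -> float:
        """Best raw cosine similarity of the query against the corpus."""
        vec = self.backend.embed(query_text)
        if is_degenerate(vec):
            return 0.0
        _, sims = self.hnsw.knn_query(vec, 1)
        return sims[0]


def minmax_normalize(values: list[float]) -> list[float]:
    lo, hi = min(values), max(values)
    if hi <= lo:
        return [0.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def retrieve(
    query_text: str,
    index: VectorIndex,
    query_id: str = "",
    k_ann: int = 10,
    k_final: int = 3,
    alpha: float = 0.5,
) -> EvidenceSet:
    """Hybrid retrieval: ANN top-``k_ann`` by cosine, re-rank by
    ``alpha * dense_norm + (1 - alpha) * bm25_norm`` (min-max within the
    candidate set), return the top ``k_final`` with ties broken by chunk_id.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    vec = index.backend.embed(query_text)
    if is_degenerate(vec):
        return EvidenceSet(query_id=query_id, candidates=[], degenerate_query=True)
    short = len(index) < k_final
    ids, sims = index.dense_top(vec, min(k_ann, len(index)))
    bm25 = index.bm25.scores(tokenize(query_text), ids)
    dense_norm = minmax_normalize(sims)
    bm25_norm = minmax_normalize([bm25[c] for c in ids])
    scored = [
        ScoredCandidate(
            chunk_id=cid,
            dense_score=sim,
            bm25_score=bm25[cid],
            fused_score=alpha * dn + (1.0 - alpha) * bn,
        )
        for cid, sim, dn, bn in zip(ids, sims, dense_norm, bm25_norm)
    ]
    scored.sort(key=lambda c: (-c.fused_score, c.chunk_id))
    return EvidenceSet(
        query_id=query_id,
        candidates=scored[:k_final],
        retrieval_trace=scored,
        short_corpus=short,
    )
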