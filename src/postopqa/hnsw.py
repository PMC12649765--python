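"""Hierarchical navigable small-world (HNSW) approximate nearest-neighbour
index over unit vectors with cosine (dot-product) similarity.

A compact NumPy implementation of the standard algorithm: exponential level
assignment with scale 1/ln(M), greedy descent through upper layers, and a
beam search of width ``ef`` on each layer.  Level 0 allows up to 2M links
per node, upper levels M.  Level draws come from a seeded generator and all
tie-breaks are by label, so builds and queries are fully deterministic.

At desk scale this is exact in the limit: with ``ef`` equal to the corpus
size the layer-0 beam search exhausts the (connected) graph and returns the
true k nearest neighbours.
"""

from __future__ import annotations

import heapq
import math

import numpy as np


class HNSWIndex:
    def __init__(
        self,
        dim: int,
        M: int = 32,
        ef_construction: int = 200,
        ef_search: int = 100,
        seed: int = 0,
    ) -> None:
        if M < 2:
            raise ValueError("M must be >= 2")
        if ef_construction < M:
            raise ValueError("ef_construction must be >= M")
        self.dim = dim
        self.M = M
        self.M0 = 2 * M
        self.ef_construction = ef_construction
        self.ef_search = ef_search
        self._mult = 1.0 / math.log(M)
        self._rng = np.random.default_rng(seed)
        self._vectors: np.ndarray = np.empty((0, dim), dtype=np.float64)
        self._labels: list[str] = []
        self._label_to_idx: dict[str, int] = {}
        # per node: list of neighbour-index lists, one per level 0..node_level
        self._links: list[list[list[int]]] = []
        self._levels: list[int] = []
        self._entry: int = -1
        self._max_level: int = -1

    def __len__(self) -> int:
        return len(self._labels)

    # ---- construction -----------------------------------------------------

    def add_items(self, vectors: np.ndarray, labels: list[str]) -> None:
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[1] != self.dim:
            raise ValueError(f"expected vectors of dimension {self.dim}")
        if len(labels) != len(vectors):
            raise ValueError("labels/vectors length mismatch")
        norms = np.linalg.norm(vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("vectors must be L2-normalized before indexing")
        self._vectors = np.vstack([self._vectors, vectors])
        for label, vec in zip(labels, vectors):
            if label in self._label_to_idx:
                raise ValueError(f"duplicate label {label!r}")
            self._insert(label, vec)

    def _insert(self, label: str, vec: np.ndarray) -> None:
        idx = len(self._labels)
        self._labels.append(label)
        self._label_to_idx[label] = idx
        level = int(-math.log(max(self._rng.random(), 1e-300)) * self._mult)
        self._levels.append(level)
        self._links.append([[] for _ in range(level + 1)])

        if self._entry < 0:
            self._entry = idx
            self._max_level = level
            return

        ep = self._entry
        # greedy descent through layers above the node's level
        for lev in range(self._max_level, level, -1):
            ep = self._greedy_step(vec, ep, lev)
        # beam search + connect on the shared layers
        for lev in range(min(level, self._max_level), -1, -1):
            candidates = self._search_layer(vec, [ep], self.ef_construction, lev)
            cap = self.M0 if lev == 0 else self.M
            neighbours = [i for _, i in heapq.nlargest(self.M, candidates)]
            self._links[idx][lev] = list(neighbours)
            for n in neighbours:
                links = self._links[n][lev]
                links.append(idx)
                if len(links) > cap:
                    sims = self._vectors[links] @ self._vectors[n]
                    order = sorted(range(len(links)), key=lambda j: (-sims[j], links[j]))
                    self._links[n][lev] = [links[j] for j in order[:cap]]
            ep = neighbours[0] if neighbours else ep
        if level > self._max_level:
            self._max_level = level
            self._entry = idx

    # ---- search -----------------------------------------------------------

    def _greedy_step(self, q: np.ndarray, ep: int, level: int) -> int:
        cur = ep
        cur_sim = float(self._vectors[cur] @ q)
        improved = True
        while improved:
            improved = False
            links = self._links[cur][level]
            if not links:
                break
            sims = self._vectors[links] @ q
            best = int(np.argmax(sims))
            if sims[best] > cur_sim:
                cur, cur_sim = links[best], float(sims[best])
                improved = True
        return cur

    def _search_layer(
        self, q: np.ndarray, entry_points: list[int], ef: int, level: int
    ) -> list[tuple[float, int]]:
        """Beam search; returns up to ``ef`` (similarity, index) pairs."""
        visited = set(entry_points)
        sims = {i: float(self._vectors[i] @ q) for i in entry_points}
        candidates = [(-sims[i], i) for i in entry_points]  # max-heap on sim
        heapq.heapify(candidates)
        result = [(sims[i], i) for i in entry_points]  # min-heap on sim
        heapq.heapify(result)
        while candidates:
            neg_sim, cur = heapq.heappop(candidates)
            if len(result) >= ef and -neg_sim < result[0][0]:
                break
            fresh = [n for n in self._links[cur][level] if n not in visited]
            if not fresh:
                continue
            visited.update(fresh)
            fresh_sims = self._vectors[fresh] @ q
            for n, s in zip(fresh, fresh_sims):
                s = float(s)
                if len(result) < ef or s > result[0][0]:
                    heapq.heappush(candidates, (-s, n))
                    heapq.heappush(result, (s, n))
                    if len(result) > ef:
                        heapq.heappop(result)
        return result

    def knn_query(
        self, query: np.ndarray, k: int, ef: int | None = None
    ) -> tuple[list[str], list[float]]:
        """Return up to ``k`` labels and cosine similarities, best first."""
        if len(self) == 0:
            raise ValueError("index is empty")
        q = np.asarray(query, dtype=np.float64)
        ef = max(ef if ef is not None else self.ef_search, k)
        ep = self._entry
        for lev in range(self._max_level, 0, -1):
            ep = self._greedy_step(q, ep, lev)
        found = self._search_layer(q, [ep], ef, 0)
        found.sort(key=lambda t: (-t[0], self._labels[t[1]]))
        top = found[:k]
        return [self._labels[i] for _, i in top], [s for s, _ in top]

    def vector_for(self, label: str) -> np.ndarray:
        return self._vectors[self._label_to_idx[label]]
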