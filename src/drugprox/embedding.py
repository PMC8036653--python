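"""Node embeddings of a protein-interaction graph (node2vec-style).

Two stages:

1. **Biased second-order random walks.**  From node ``v``, having arrived
   from ``t``, the unnormalised probability of stepping to neighbour ``x``
   is ``weight(v, x) * b`` with bias ``b = 1/p`` if ``x == t`` (return),
   ``1`` if ``x`` is adjacent to ``t``, and ``1/q`` otherwise.  With
   ``p = q = 1`` this reduces exactly to the first-order weighted walk.

2. **Skip-gram with negative sampling (SGNS)** trained on the walk corpus.
   Implemented here directly in numpy: pairs are drawn with the classic
   reduced-window rule (per-centre window size uniform on ``1..window``),
   negatives from the unigram^0.75 distribution, and SGD runs on
   minibatches with a linearly decaying learning rate.  Training is
   single-threaded and bit-reproducible given the seed.

Similar embedding vectors (cosine similarity) indicate nodes that co-occur
on walks, i.e. are close in the network -- the quantity the repositioning
stage scores.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.special import expit


@dataclasses.dataclass(frozen=True)
class WalkParams:
    """Random-walk parameters: return bias ``p``, in-out bias ``q``."""

    p: float = 1.0
    q: float = 1.0
    num_walks_per_node: int = 10
    walk_length: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.p > 0 and self.q > 0):
            raise ValueError("p and q must be positive")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.num_walks_per_node < 1:
            raise ValueError("num_walks_per_node must be >= 1")


@dataclasses.dataclass(frozen=True)
class TrainParams:
    """SGNS hyper-parameters (word2vec-style defaults)."""

    dimension: int = 128
    window: int = 10
    epochs: int = 5
    negative_samples: int = 5
    initial_lr: float = 0.025
    min_lr: float = 1e-4
    batch_size: int = 2048
    #: embedding rows are rescaled to this norm when SGD pushes them past
    #: it; bounds the divergence that delayed (minibatched) saturation
    #: feedback can otherwise cause on small, dense corpora
    max_norm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.epochs < 1 or self.negative_samples < 1:
            raise ValueError("epochs and negative_samples must be >= 1")


class EmbeddingMatrix:
    """Per-node embedding vectors.

    ``nodes`` is the ordered node list, ``matrix`` the (V, d) float array
    of vectors, ``skipped`` the nodes that received no vector (never
    reached by a walk).
    """

    def __init__(self, nodes: Sequence[str], matrix: np.ndarray, skipped: Iterable[str] = ()):
        if len(nodes) != matrix.shape[0]:
            raise ValueError("node list and matrix row count differ")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("embedding matrix contains non-finite values")
        self.nodes = list(nodes)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        self.skipped = frozenset(skipped)
        self._index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __getitem__(self, node: str) -> np.ndarray:
        return self.matrix[self._index[node]]

    def vectors_for(self, nodes: Iterable[str]) -> tuple[list[str], np.ndarray]:
        """Vectors of the given nodes, restricted to embedded ones.

        Returns (present node list in lexicographic order, matrix).
        """
        present = sorted(n for n in set(nodes) if n in self._index)
        rows = [self._index[n] for n in present]
        return present, self.matrix[rows]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node\t" + "\t".join(f"v{i + 1}" for i in range(self.d)) + "\n")
            for n in self.nodes:
                vec = "\t".join(f"{x:.8g}" for x in self[n])
                fh.write(f"{n}\t{vec}\n")

    @classmethod
    def from_tsv(cls, path) -> "EmbeddingMatrix":
        nodes, rows = [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("node\t"):
                raise ValueError("not an embedding TSV (missing header)")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                nodes.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        return cls(nodes, np.array(rows, dtype=np.float64))


# ---------------------------------------------------------------------------
# graph construction


def build_graph(edges) -> nx.Graph:
    """Build an undirected simple graph from an edge list.

    ``edges`` is either a path to a 2- or 3-column (weighted) TSV or an
    iterable of ``(u, v)`` / ``(u, v, weight)`` tuples.  Duplicate edges
    keep the maximum weight; self-loops are dropped with a warning; node
    order is lexicographic.
    """
    if isinstance(edges, (str, bytes)) or hasattr(edges, "__fspath__"):
        records = []
        with open(edges) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) == 2:
                    records.append((fields[0], fields[1]))
                elif len(fields) == 3:
                    try:
                        records.append((fields[0], fields[1], float(fields[2])))
                    except ValueError as exc:
                        raise ValueError(f"malformed edge weight on line {lineno}: {line!r}") from exc
                else:
                    raise ValueError(f"malformed edge list line {lineno}: {line!r}")
    else:
        records = list(edges)

    best: dict[tuple[str, str], float | None] = {}
    nodes: set[str] = set()
    dropped_loops = 0
    for rec in records:
        if len(rec) == 2:
            u, v = rec
            w = None
        else:
            u, v, w = rec
            if w is not None and w <= 0:
                raise ValueError(f"non-positive edge weight on {rec!r}")
        u, v = str(u), str(v)
        nodes.update((u, v))
        if u == v:
            dropped_loops += 1
            continue
        key = (u, v) if u < v else (v, u)
        prev = best.get(key)
        if key not in best or (w is not None and (prev is None or w > prev)):
            best[key] = w
    if dropped_loops:
        warnings.warn(f"dropped {dropped_loops} self-loop(s)")
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for (u, v), w in sorted(best.items()):
        if w is None:
            g.add_edge(u, v)
        else:
            g.add_edge(u, v, weight=w)
    return g


# ---------------------------------------------------------------------------
# walks


def generate_walks(graph: nx.Graph, params: WalkParams) -> list[list[str]]:
    """Sample the biased random-walk corpus.

    ``num_walks_per_node`` walks start at every node (start order shuffled
    per round, seeded); each walk runs to ``walk_length`` nodes, stopping
    early at dead ends.  Deterministic given the seed.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("cannot walk on an empty graph")
    index = {n: i for i, n in enumerate(nodes)}
    nbrs: list[np.ndarray] = []
    cumw: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for n in nodes:
        nb = sorted(graph.neighbors(n))
        nbrs.append(np.array([index[x] for x in nb], dtype=np.int64))
        w = np.array([graph[n][x].get("weight", 1.0) for x in nb], dtype=np.float64)
        weights.append(w)
        cumw.append(np.cumsum(w))

    rng = np.random.default_rng(params.seed)
    first_order = params.p == 1.0 and params.q == 1.0
    inv_p, inv_q = 1.0 / params.p, 1.0 / params.q
    walks: list[list[str]] = []
    for _ in range(params.num_walks_per_node):
        for start in rng.permutation(len(nodes)):
            cur = int(start)
            walk = [cur]
            prev = -1
            while len(walk) < params.walk_length:
                nb = nbrs[cur]
                if nb.size == 0:
                    break
                if first_order or prev < 0:
                    cw = cumw[cur]
                else:
                    bias = np.full(nb.size, inv_q)
                    bias[np.isin(nb, nbrs[prev], assume_unique=True)] = 1.0
                    bias[nb == prev] = inv_p
                    cw = np.cumsum(weights[cur] * bias)
                j = int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))
                j = min(j, nb.size - 1)
                prev, cur = cur, int(nb[j])
                walk.append(cur)
            walks.append([nodes[i] for i in walk])
    return walks


def step_distribution(
    graph: nx.Graph, prev: str | None, current: str, params: WalkParams
) -> dict[str, float]:
    """Exact one-step transition distribution of the biased walk.

    Used as the analytic reference for the sampler (the probabilities sum
    to 1 over the neighbour set).
    """
    nb = sorted(graph.neighbors(current))
    if not nb:
        return {}
    w = np.array([graph[current][x].get("weight", 1.0) for x in nb], dtype=float)
    if prev is not None:
        prev_nb = set(graph.neighbors(prev))
        bias = np.array(
            [
                1.0 / params.p if x == prev else (1.0 if x in prev_nb else 1.0 / params.q)
                for x in nb
            ]
        )
        w = w * bias
    w = w / w.sum()
    return dict(zip(nb, w))


# ---------------------------------------------------------------------------
# skip-gram with negative sampling


def _epoch_pairs(
    walks_idx: list[np.ndarray], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) index pairs for one epoch with reduced windows."""
    centers, contexts = [], []
    for wi in rng.permutation(len(walks_idx)):
        walk = walks_idx[wi]
        L = walk.size
        if L < 2:
            continue
        b = rng.integers(1, window + 1, size=L)
        for off in range(1, min(window, L - 1) + 1):
            right = np.nonzero(b[: L - off] >= off)[0]
            if right.size:
                centers.append(walk[right])
                contexts.append(walk[right + off])
            left = np.nonzero(b[off:] >= off)[0]
            if left.size:
                centers.append(walk[left + off])
                contexts.append(walk[left])
    if not centers:
        raise ValueError("corpus yields no training pairs (all walks length < 2)")
    return np.concatenate(centers), np.concatenate(contexts)


def train_embeddings(
    corpus: Sequence[Sequence[str]], params: TrainParams
) -> EmbeddingMatrix:
    """Train SGNS vectors on a walk corpus.

    Only nodes present in the corpus receive vectors.  Deterministic given
    the seed (single-threaded minibatch SGD; within-batch updates are
    accumulated, which is the minibatch analogue of asynchronous SGD).
    """
    if not corpus:
        raise ValueError("empty walk corpus")
    # only walks of length >= 2 produce training pairs; nodes seen solely
    # in singleton walks (isolated nodes) get no vector
    vocab = sorted({n for walk in corpus if len(walk) >= 2 for n in walk})
    if not vocab:
        raise ValueError("corpus yields no training pairs (all walks length < 2)")
    index = {n: i for i, n in enumerate(vocab)}
    V, d = len(vocab), params.dimension
    walks_idx = [
        np.array([index[n] for n in walk], dtype=np.int64)
        for walk in corpus
        if len(walk) >= 2
    ]

    freq = np.zeros(V, dtype=np.float64)
    for walk in walks_idx:
        np.add.at(freq, walk, 1.0)
    noise = freq**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(params.seed)
    W = ((rng.random((V, d)) - 0.5) / d).astype(np.float32)
    C = np.zeros((V, d), dtype=np.float32)

    k = params.negative_samples
    B = params.batch_size
    total_est = None
    processed = 0
    for _ in range(params.epochs):
        centers, contexts = _epoch_pairs(walks_idx, params.window, rng)
        n_pairs = centers.size
        if total_est is None:
            total_est = n_pairs * params.epochs
        for s in range(0, n_pairs, B):
            c = centers[s : s + B]
            o = contexts[s : s + B]
            bsz = c.size
            lr = max(
                params.min_lr,
                params.initial_lr * (1.0 - processed / max(total_est, 1)),
            )
            neg = np.searchsorted(noise_cdf, rng.random((bsz, k)))
            tgt = np.concatenate([o[:, None], neg], axis=1)  # (b, 1+k)
            Wc = W[c]  # (b, d)
            Ct = C[tgt]  # (b, 1+k, d)
            dots = np.einsum("bd,bkd->bk", Wc, Ct)
            g = -expit(dots)
            g[:, 0] += 1.0  # positive label on the true context
            g *= lr
            g = g.astype(np.float32)
            dW = np.einsum("bk,bkd->bd", g, Ct)
            dC = g[:, :, None] * Wc[:, None, :]
            np.add.at(W, c, dW)
            np.add.at(C, tgt.reshape(-1), dC.reshape(-1, d))
            processed += bsz
            for M in (W, C):
                norms = np.linalg.norm(M, axis=1)
                over = norms > params.max_norm
                if over.any():
                    M[over] *= (params.max_norm / norms[over])[:, None]
    return EmbeddingMatrix(vocab, W.astype(np.float64))


def embed_graph(
    graph: nx.Graph,
    walk_params: WalkParams = WalkParams(),
    train_params: TrainParams = TrainParams(),
) -> EmbeddingMatrix:
    """Walks + SGNS in one call; nodes never visited are recorded as skipped."""
    corpus = generate_walks(graph, walk_params)
    emb = train_embeddings(corpus, train_params)
    skipped = set(graph.nodes).difference(emb.nodes)
    if skipped:
        warnings.warn(f"{len(skipped)} node(s) received no embedding (never walked)")
    return EmbeddingMatrix(emb.nodes, emb.matrix, skipped=skipped)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))
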