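"""Interaction-network node embedding from diffusion-walk sequences.

Each gene's network neighborhood is summarised in a fixed-dimension
(default 32) numeric vector.  Per source node, a random diffusion subgraph
is grown — repeatedly pick a uniformly random already-included node and a
uniformly random not-yet-included neighbor of it — and the doubled-edge
Euler circuit of the resulting tree is emitted as one sentence.  A
skip-gram model with negative sampling is then trained on the sentence
corpus so that graph-proximal genes receive similar vectors.  The
embedding is a property of the network only and is shared across cancer
types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd

__all__ = ["WalkCorpus", "load_edge_list", "generate_walks",
           "train_embedding", "embed_network", "feature_names"]

logger = logging.getLogger(__name__)


def feature_names(d: int = 32) -> list[str]:
    return [f"net_emb_{i}" for i in range(1, d + 1)]


def load_edge_list(path, universe: list[str] | None = None) -> nx.Graph:
    """Read a 2-column TSV of gene symbols into an undirected graph.

    Self-loops and duplicate (including reversed) edges are dropped with a
    logged count.  Nodes are the union of the edge endpoints and the
    optional universe list, so isolated genes stay in the graph.
    """
    g = nx.Graph()
    if universe is not None:
        g.add_nodes_from(universe)
    n_self = n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated "
                    f"symbols, got {line!r}")
            u, v = parts
            if u == v:
                n_self += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
    if n_self or n_dup:
        logger.info("load_edge_list: dropped %d self-loops, %d duplicate edges",
                    n_self, n_dup)
    return g


@dataclass
class WalkCorpus:
    """Sentences of gene symbols plus the walk parameters that made them."""

    sequences: list[list[str]]
    walks_per_node: int
    subgraph_size: int
    seed: int
    n_isolated: int = field(default=0)


def _diffusion_walk(adj: dict[int, list[int]], src: int, size: int,
                    rng: np.random.Generator) -> list[int]:
    """Grow one diffusion subgraph from ``src`` and return its Euler tour.

    The subgraph is a random tree: at each step a uniformly random
    included node that still has outside neighbors donates a uniformly
    random outside neighbor.  The emitted sequence is a depth-first
    traversal visiting every tree edge twice (an Euler circuit of the
    doubled tree), starting and ending at the source.
    """
    in_set = {src}
    children: dict[int, list[int]] = {src: []}
    # candidates: included nodes whose cached neighbor list may still
    # contain outside nodes; stale entries are removed lazily on draw
    cand: list[int] = [src]
    pool: dict[int, list[int]] = {src: list(adj[src])}

    while len(in_set) < size and cand:
        ci = int(rng.integers(len(cand)))
        u = cand[ci]
        lst = pool[u]
        w = -1
        while lst:
            wi = int(rng.integers(len(lst)))
            lst[wi], lst[-1] = lst[-1], lst[wi]
            x = lst.pop()
            if x not in in_set:
                w = x
                break
        if w < 0:                      # u exhausted
            cand[ci] = cand[-1]
            cand.pop()
            continue
        in_set.add(w)
        children[u].append(w)
        children[w] = []
        cand.append(w)
        pool[w] = list(adj[w])

    # iterative DFS emitting node on entry and on each return
    seq = [src]
    stack = [(src, iter(children[src]))]
    while stack:
        node, it = stack[-1]
        child = next(it, None)
        if child is None:
            stack.pop()
            if stack:
                seq.append(stack[-1][0])
        else:
            seq.append(child)
            stack.append((child, iter(children[child])))
    return seq


def generate_walks(network: nx.Graph, walks_per_node: int = 10,
                   subgraph_size: int = 40, seed: int = 0) -> WalkCorpus:
    """Diffusion-walk corpus: ``walks_per_node`` sentences per source node.

    Isolated nodes yield singleton sequences (logged); every non-isolated
    node therefore appears in at least ``walks_per_node`` sentences as
    the source.
    """
    if subgraph_size < 2:
        raise ValueError(f"subgraph_size must be >= 2, got {subgraph_size}")
    if walks_per_node < 1:
        raise ValueError("walks_per_node must be >= 1")
    nodes = list(network.nodes())
    idx = {g: i for i, g in enumerate(nodes)}
    adj = {idx[g]: [idx[n] for n in network.neighbors(g)] for g in nodes}
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))

    sequences: list[list[str]] = []
    n_isolated = 0
    for g in nodes:
        i = idx[g]
        if not adj[i]:
            n_isolated += 1
            for _ in range(walks_per_node):
                sequences.append([g])
            continue
        for _ in range(walks_per_node):
            walk = _diffusion_walk(adj, i, subgraph_size, rng)
            sequences.append([nodes[j] for j in walk])
    if n_isolated:
        logger.info("generate_walks: %d isolated nodes produced singleton "
                    "sequences", n_isolated)
    return WalkCorpus(sequences, walks_per_node, subgraph_size, seed, n_isolated)


def _skipgram_pairs(seqs: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for s in seqs:
        n = s.size
        for off in range(1, min(window, n - 1) + 1):
            if n - off <= 0:
                continue
            a, b = s[:-off], s[off:]
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
    if not centers:
        z = np.empty(0, dtype=np.int64)
        return z, z
    return np.concatenate(centers), np.concatenate(contexts)


def train_embedding(corpus: WalkCorpus, d: int = 32, window: int = 5,
                    epochs: int = 5, seed: int = 0, negative: int = 5,
                    learning_rate: float = 0.025,
                    batch_size: int = 4096) -> pd.DataFrame:
    """Skip-gram-with-negative-sampling embedding of the walk corpus.

    Minibatch SGD with a linearly decaying learning rate; negatives are
    drawn from the unigram distribution raised to 3/4.  Training is
    single-threaded and fully deterministic for a given seed.  Nodes that
    never occur in a context pair (e.g. isolated nodes with singleton
    sentences) receive the zero vector.
    """
    if d < 1:
        raise ValueError(f"embedding dimension must be >= 1, got {d}")
    if not corpus.sequences:
        raise ValueError("corpus is empty")

    vocab = sorted({g for s in corpus.sequences for g in s})
    vid = {g: i for i, g in enumerate(vocab)}
    nv = len(vocab)
    seqs = [np.fromiter((vid[g] for g in s), dtype=np.int64, count=len(s))
            for s in corpus.sequences]

    centers, contexts = _skipgram_pairs(seqs, window)
    cols = feature_names(d)
    if centers.size == 0:
        logger.info("train_embedding: no context pairs; returning zero matrix")
        return pd.DataFrame(np.zeros((nv, d)), index=pd.Index(vocab, name="gene"),
                            columns=cols)

    counts = np.bincount(np.concatenate(seqs), minlength=nv).astype(float)
    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(102,)))
    # float32 halves memory traffic in the gather/scatter-bound updates
    w_in = ((rng.random((nv, d)) - 0.5) / d).astype(np.float32)
    w_out = np.zeros((nv, d), dtype=np.float32)

    n_pairs = centers.size
    total_steps = epochs * n_pairs
    step = 0
    # minibatch accumulation approximates sequential SGD only while index
    # collisions per batch stay modest; cap the batch for small vocabularies
    eff_batch = int(min(batch_size, max(64, 2 * nv)))
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, eff_batch):
            sel = order[start:start + eff_batch]
            c, t = centers[sel], contexts[sel]
            lr = learning_rate * max(1.0 - step / total_steps, 1e-4)
            step += sel.size

            neg = np.searchsorted(noise_cdf, rng.random((sel.size, negative)))
            lr = np.float32(lr)
            v = w_in[c]                                  # (B, d)
            u_pos = w_out[t]                             # (B, d)
            u_neg = w_out[neg]                           # (B, k, d)

            g_pos = _sigmoid(np.einsum("bd,bd->b", v, u_pos)) - np.float32(1.0)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, u_neg))

            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            np.add.at(w_in, c, -lr * grad_v)
            np.add.at(w_out, t, -lr * g_pos[:, None] * v)
            np.add.at(w_out, neg.reshape(-1),
                      (-lr * g_neg[..., None] * v[:, None, :]).reshape(-1, d))

    # zero out nodes that contributed no context pair
    seen = np.zeros(nv, dtype=bool)
    seen[centers] = True
    seen[contexts] = True
    w_in[~seen] = 0.0
    if (~seen).any():
        logger.info("train_embedding: %d nodes had no context pairs; zero "
                    "vectors assigned", int((~seen).sum()))
    return pd.DataFrame(w_in.astype(np.float64),
                        index=pd.Index(vocab, name="gene"), columns=cols)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def embed_network(network: nx.Graph, d: int = 32, walks_per_node: int = 10,
                  subgraph_size: int = 40, window: int = 5, epochs: int = 5,
                  seed: int = 0) -> pd.DataFrame:
    """End-to-end: walks then skip-gram; one row per network node."""
    corpus = generate_walks(network, walks_per_node, subgraph_size, seed)
    emb = train_embedding(corpus, d=d, window=window, epochs=epochs, seed=seed)
    # every network node gets a row (isolated nodes may be vocab-only)
    emb = emb.reindex(sorted(network.nodes()), fill_value=0.0)
    emb.index.name = "gene"
    return emb
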