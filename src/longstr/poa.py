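"""Partial-order alignment (POA) multiple alignment and consensus.

A cluster's event sequences are progressively aligned into a DAG of bases:
the first (longest) sequence seeds a linear chain, and each subsequent
sequence is globally aligned against the graph with dynamic programming
over the topological order, then fused in — matched positions increment
node weights, unmatched positions add branch nodes and edges. The
consensus is the maximum-total-node-weight source-to-sink path, which
implements per-column majority voting and so cancels most of the random
per-read sequencing error.

Scoring is linear-gap with defaults {match +2, mismatch -4, gap -4};
``N`` matches nothing (scored as mismatch).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

NEG_INF = np.iinfo(np.int64).min // 4  # safe "minus infinity" for int DP


@dataclass(frozen=True)
class PoaScores:
    match: int = 2
    mismatch: int = -4
    gap: int = -4

    def __post_init__(self) -> None:
        if not (self.match > 0 and self.mismatch < 0 and self.gap < 0):
            raise ValueError("require match > 0, mismatch < 0, gap < 0")


@dataclass
class ConsensusResult:
    sequence: str
    n_inputs: int
    mean_support: float  # average node weight along the consensus path


class PoaGraph:
    """DAG of single bases with read-support weights on nodes and edges."""

    def __init__(self) -> None:
        self.bases: list[str] = []
        self.weights: list[int] = []
        self.edges_in: list[dict[int, int]] = []  # node -> {pred: edge weight}
        self.edges_out: list[dict[int, int]] = []
        self.aligned: list[set[int]] = []  # same-column nodes (other bases)
        self.n_inputs = 0

    def __len__(self) -> int:
        return len(self.bases)

    def add_node(self, base: str) -> int:
        self.bases.append(base)
        self.weights.append(0)
        self.edges_in.append({})
        self.edges_out.append({})
        self.aligned.append(set())
        return len(self.bases) - 1

    def add_edge(self, u: int, v: int) -> None:
        self.edges_out[u][v] = self.edges_out[u].get(v, 0) + 1
        self.edges_in[v][u] = self.edges_in[v].get(u, 0) + 1

    def topological_order(self) -> list[int]:
        """Kahn's algorithm with a min-heap for a deterministic order."""
        indeg = [len(p) for p in self.edges_in]
        heap = [v for v in range(len(self)) if indeg[v] == 0]
        heapq.heapify(heap)
        order: list[int] = []
        while heap:
            v = heapq.heappop(heap)
            order.append(v)
            for w in self.edges_out[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    heapq.heappush(heap, w)
        if len(order) != len(self):
            raise RuntimeError("POA graph is not a DAG")
        return order

    def sources(self) -> list[int]:
        return [v for v in range(len(self)) if not self.edges_in[v]]

    def sinks(self) -> list[int]:
        return [v for v in range(len(self)) if not self.edges_out[v]]


def align_to_graph(
    graph: PoaGraph, seq: str, scores: PoaScores = PoaScores()
) -> list[tuple[int | None, int | None]]:
    """Global DP alignment of ``seq`` against the graph.

    Returns the alignment path as (node_id, seq_index) pairs in order:
    (v, i) is a match/mismatch, (v, None) a deletion (node skipped by the
    sequence), (None, i) an insertion (sequence base absent from the
    path). The path consumes a full source-to-sink walk of the graph and
    the whole sequence; it is optimal under the scoring scheme.
    """
    if not seq:
        raise ValueError("cannot align an empty sequence")
    if len(graph) == 0:
        # initialization case: caller turns seq into a linear chain
        return [(None, i) for i in range(len(seq))]

    m = len(seq)
    order = graph.topological_order()
    topo_pos = {v: t for t, v in enumerate(order)}
    g = scores.gap
    idx = np.arange(m + 1, dtype=np.int64)
    src_row = g * idx  # virtual source: leading insertions
    S = np.empty((len(graph), m + 1), dtype=np.int64)

    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_code = ord("N")

    def sub_scores(base: str) -> np.ndarray:
        b = ord(base)
        hit = (seq_arr == b) & (seq_arr != n_code) if b != n_code else np.zeros(m, bool)
        return np.where(hit, scores.match, scores.mismatch).astype(np.int64)

    for v in order:
        preds = list(graph.edges_in[v])
        if preds:
            pred_best = S[preds[0]].copy() if len(preds) == 1 else np.max(S[preds], axis=0)
        else:
            pred_best = src_row
        base_cand = pred_best + g  # deletion: consume node, no seq char
        match_cand = pred_best[:-1] + sub_scores(graph.bases[v])
        np.maximum(base_cand[1:], match_cand, out=base_cand[1:])
        # insertions within the row: S[v][i] = max_{j<=i} base[j] + (i-j)*g
        t = base_cand - g * idx
        np.maximum.accumulate(t, out=t)
        S[v] = t + g * idx

    sinks = graph.sinks()
    end = min(sinks, key=lambda v: (-S[v][m], topo_pos[v]))

    # traceback; preference match > deletion > insertion, predecessors in
    # ascending id, all deterministic
    path: list[tuple[int | None, int | None]] = []
    v, i = end, m
    while True:
        score = S[v][i]
        preds = sorted(graph.edges_in[v])
        subs = None
        if i > 0:
            b, c = graph.bases[v], seq[i - 1]
            subs = scores.match if (b == c and b != "N") else scores.mismatch
        moved = False
        if i > 0:
            for p in preds:
                if S[p][i - 1] + subs == score:
                    path.append((v, i - 1))
                    v, i = p, i
                    i -= 1
                    moved = True
                    break
            if not moved and not preds and src_row[i - 1] + subs == score:
                path.append((v, i - 1))
                for j in range(i - 2, -1, -1):
                    path.append((None, j))
                break
        if moved:
            continue
        for p in preds:
            if S[p][i] + scores.gap == score:
                path.append((v, None))
                v = p
                moved = True
                break
        if moved:
            continue
        if not preds and src_row[i] + scores.gap == score:
            path.append((v, None))
            for j in range(i - 1, -1, -1):
                path.append((None, j))
            break
        if i > 0 and S[v][i - 1] + scores.gap == score:
            path.append((None, i - 1))
            i -= 1
            continue
        raise RuntimeError("POA traceback failed (inconsistent DP matrix)")
    path.reverse()
    return path


def _fuse(graph: PoaGraph, seq: str, path: list[tuple[int | None, int | None]]) -> None:
    """Thread one aligned sequence into the graph, updating weights."""
    prev_node: int | None = None
    for node, i in path:
        if i is None:
            continue  # deletion: node not used by this sequence
        c = seq[i]
        target: int | None = None
        if node is not None:
            if graph.bases[node] == c:
                target = node
            else:
                # same alignment column: reuse an existing branch node with
                # this base so weights accumulate across reads
                for alt in sorted(graph.aligned[node]):
                    if graph.bases[alt] == c:
                        target = alt
                        break
        if target is None:
            target = graph.add_node(c)
            if node is not None:
                column = graph.aligned[node] | {node}
                graph.aligned[target] = set(column)
                for other in column:
                    graph.aligned[other].add(target)
        graph.weights[target] += 1
        if prev_node is not None:
            graph.add_edge(prev_node, target)
        prev_node = target


def build_graph(seqs: list[str], scores: PoaScores = PoaScores()) -> PoaGraph:
    """Progressively build a POA graph from sequences, longest first.

    The longest sequence seeds the backbone so the expansion is covered
    end to end; the sort is stable, so equal-length inputs keep the
    caller's order (callers pass them pre-sorted by read id).
    """
    seqs = [s for s in seqs if s]
    if not seqs:
        raise ValueError("build_graph requires at least one non-empty sequence")
    graph = PoaGraph()
    for seq in sorted(seqs, key=len, reverse=True):
        path = align_to_graph(graph, seq, scores)
        _fuse(graph, seq, path)
        graph.n_inputs += 1
    return graph


def consensus(graph: PoaGraph) -> ConsensusResult:
    """Heaviest-bundle source-to-sink path of the graph.

    The consensus path maximizes the total traversed edge weight (the
    number of read traversals of each junction), which is what
    per-column majority voting looks like on the graph: a
    sequencing-error branch or insertion detour carries one or two read
    traversals and loses against the direct edge carried by the read
    majority. Maximizing summed *node* weights instead would greedily
    include every one-read insertion node that lengthens the path,
    inflating the consensus under indel noise. Ties prefer the
    higher-weight incoming edge, then the lexicographically smaller
    base, then the smaller node id.
    """
    if len(graph) == 0 or graph.n_inputs < 1:
        raise ValueError("consensus requires a graph built from >= 1 sequence")
    order = graph.topological_order()
    best: dict[int, int] = {}
    back: dict[int, int | None] = {}
    for v in order:
        choice: int | None = None
        choice_key = None
        for p, ew in graph.edges_in[v].items():
            key = (best[p] + ew, ew, -ord(graph.bases[p]), -p)
            if choice_key is None or key > choice_key:
                choice, choice_key = p, key
        best[v] = choice_key[0] if choice is not None else 0
        back[v] = choice
    end = max(
        graph.sinks(), key=lambda v: (best[v], -ord(graph.bases[v]), -v)
    )
    path: list[int] = []
    node: int | None = end
    while node is not None:
        path.append(node)
        node = back[node]
    path.reverse()
    seq = "".join(graph.bases[v] for v in path)
    mean_support = float(np.mean([graph.weights[v] for v in path]))
    return ConsensusResult(sequence=seq, n_inputs=graph.n_inputs, mean_support=mean_support)


def consensus_of(seqs: list[str], scores: PoaScores = PoaScores()) -> ConsensusResult:
    """Convenience: build the graph and return its consensus."""
    return consensus(build_graph(seqs, scores))
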