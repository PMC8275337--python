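"""Knowledge-graph construction from shared protein clusters.

For every candidate sequence pair (at least one shared protein cluster)
two weights are computed:

* ``P_weight = -log10( P(y >= c) * C(N, 2) )`` — the hypergeometric
  probability that two sequences carrying ``a`` and ``b`` of the ``n``
  protein clusters share at least the observed ``c`` clusters, scaled by
  the number of sequence pairs in the run (a Bonferroni-style expected
  count).  Large positive values mean the shared-gene content is far
  beyond chance.
* ``E_weight`` — the significance of the shared proteins themselves:
  ``S(A,B) = -log10(mean E-value)`` over the shared-protein alignments,
  kept only for each node's top-k partners by S (k = 5 by default).

An edge exists when ``P_weight + E_weight > tau`` (strictly; tau = 1 by
default).  Unlabeled nodes whose connected component contains no labeled
reference are rejected: the classifier will not output a prediction for
them, which is what lets the method refuse out-of-scope sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .align import AlignmentHit, EVALUE_FLOOR
from .cluster import ProteinClusterSet

__all__ = [
    "EdgeScore",
    "KnowledgeGraph",
    "shared_cluster_count",
    "prob_shared_at_least",
    "p_weight",
    "mean_similarity",
    "score_edges",
    "top_k_edge_filter",
    "build_knowledge_graph",
]

P_WEIGHT_CAP = 300.0
LOG10_E = math.log10(math.e)


def shared_cluster_count(
    seq_a: str, seq_b: str, clusters: ProteinClusterSet
) -> tuple[int, int, int]:
    """(a, b, c): distinct cluster counts of each sequence and the overlap."""
    ca = clusters.clusters_of(seq_a)
    cb = clusters.clusters_of(seq_b)
    return len(ca), len(cb), len(ca & cb)


def prob_shared_at_least(a: int, b: int, c: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(y >= c).

    Probability that two sequences containing ``a`` and ``b`` of ``n``
    equally likely protein clusters share at least ``c`` of them.
    """
    if not (0 <= a <= n and 0 <= b <= n):
        raise ValueError(f"require 0 <= a,b <= n; got a={a}, b={b}, n={n}")
    if c < 0:
        raise ValueError("c must be >= 0")
    if c == 0:
        return 1.0
    if c > min(a, b):
        return 0.0
    return float(hypergeom.sf(c - 1, n, a, b))


def _log10_prob_shared_at_least(a: int, b: int, c: int, n: int) -> float:
    """log10 of the upper tail, stable far below float underflow."""
    if c == 0:
        return 0.0
    if c > min(a, b):
        return -math.inf
    return float(hypergeom.logsf(c - 1, n, a, b)) * LOG10_E


def p_weight(prob: float, N: int, cap: float = P_WEIGHT_CAP) -> float:
    """``-log10(prob * C(N, 2))``; capped when the probability underflows.

    May be negative when the expected number of sequence pairs sharing
    at least ``c`` clusters exceeds 1 (an insignificant overlap).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not (0.0 <= prob <= 1.0):
        raise ValueError("prob must lie in [0, 1]")
    if prob == 0.0:
        return cap
    value = -(math.log10(prob) + math.log10(math.comb(N, 2)))
    return min(value, cap)


def _p_weight_from_log10(log10_prob: float, N: int, cap: float = P_WEIGHT_CAP) -> float:
    if log10_prob == -math.inf:
        return cap
    return min(-(log10_prob + math.log10(math.comb(N, 2))), cap)


def mean_similarity(
    seq_a: str,
    seq_b: str,
    hits: Iterable[AlignmentHit],
    clusters: ProteinClusterSet,
    evalue_floor: float = EVALUE_FLOOR,
) -> float:
    """S(A, B): -log10 of the mean E-value over shared-protein alignments.

    A shared-protein alignment is a retained hit between a protein of A
    and a protein of B that lie in the same cluster.  Returns 0 when no
    such alignment exists.
    """
    evs = _shared_hit_evalues(seq_a, seq_b, hits, clusters, evalue_floor)
    if not evs:
        return 0.0
    return -math.log10(sum(evs) / len(evs))


def _shared_hit_evalues(
    seq_a: str,
    seq_b: str,
    hits: Iterable[AlignmentHit],
    clusters: ProteinClusterSet,
    evalue_floor: float = EVALUE_FLOOR,
) -> list[float]:
    evs = []
    for h in hits:
        pa, pb = h.query_parent, h.subject_parent
        if {pa, pb} != {seq_a, seq_b}:
            continue
        mq = clusters.membership.get(h.query_id)
        ms = clusters.membership.get(h.subject_id)
        if mq is None or ms is None or mq != ms:
            continue
        evs.append(max(h.evalue, evalue_floor))
    return evs


@dataclass(frozen=True)
class EdgeScore:
    seq_a: str
    seq_b: str
    c: int
    n_shared_hits: int
    p_weight: float
    e_weight: float
    s: float


def score_edges(
    seq_ids: Sequence[str],
    clusters: ProteinClusterSet,
    hits: Iterable[AlignmentHit],
    N: int | None = None,
    evalue_floor: float = EVALUE_FLOOR,
    p_cap: float = P_WEIGHT_CAP,
) -> list[EdgeScore]:
    """Score every candidate pair (>= 1 shared cluster) among ``seq_ids``.

    ``N`` defaults to ``len(seq_ids)`` — the number of sequences in the
    run, giving the C(N, 2) pair count of the P-weight.  ``e_weight`` is
    initialised to ``s``; apply :func:`top_k_edge_filter` afterwards.
    """
    if N is None:
        N = len(seq_ids)
    n = clusters.n
    # bucket hits by unordered parent pair once
    hits_by_pair: dict[frozenset[str], list[AlignmentHit]] = {}
    for h in hits:
        if h.query_parent != h.subject_parent:
            hits_by_pair.setdefault(frozenset((h.query_parent, h.subject_parent)), []).append(h)
    scores: list[EdgeScore] = []
    ids = sorted(set(seq_ids))
    memberships = {s: clusters.clusters_of(s) for s in ids}
    for i, sa in enumerate(ids):
        ca = memberships[sa]
        if not ca:
            continue
        for sb in ids[i + 1 :]:
            cb = memberships[sb]
            shared = ca & cb
            if not shared:
                continue
            c = len(shared)
            lp = _log10_prob_shared_at_least(len(ca), len(cb), c, n)
            pw = _p_weight_from_log10(lp, N, cap=p_cap)
            pair_hits = hits_by_pair.get(frozenset((sa, sb)), [])
            evs = _shared_hit_evalues(sa, sb, pair_hits, clusters, evalue_floor)
            s = -math.log10(sum(evs) / len(evs)) if evs else 0.0
            scores.append(
                EdgeScore(
                    seq_a=sa,
                    seq_b=sb,
                    c=c,
                    n_shared_hits=len(evs),
                    p_weight=pw,
                    e_weight=s,
                    s=s,
                )
            )
    return scores


def top_k_edge_filter(scores: Sequence[EdgeScore], k: int = 5) -> list[EdgeScore]:
    """Keep E-weights only for each node's top-k partners ranked by S.

    An edge keeps its E-weight if it is ranked within the top k from
    either endpoint's perspective (union semantics); otherwise E_weight
    is zeroed while P_weight is untouched.  Ties at the cut rank break by
    lexicographic partner id.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    partners: dict[str, list[tuple[float, str, int]]] = {}
    for idx, sc in enumerate(scores):
        partners.setdefault(sc.seq_a, []).append((-sc.s, sc.seq_b, idx))
        partners.setdefault(sc.seq_b, []).append((-sc.s, sc.seq_a, idx))
    kept: set[int] = set()
    for node, cand in partners.items():
        cand.sort()
        kept.update(idx for _, _, idx in cand[:k])
    return [
        sc if i in kept else replace(sc, e_weight=0.0)
        for i, sc in enumerate(scores)
    ]


@dataclass
class KnowledgeGraph:
    """Node-feature-attributed graph fed to the graph convolutional net.

    ``node_ids``/``features``/``labels`` cover the accepted nodes only
    (all references plus contigs connected to at least one reference
    component); ``rejected`` lists contigs for which no prediction will
    be made.
    """

    node_ids: list[str]
    features: np.ndarray  # (N, d)
    labels: list[str | None]
    adjacency: np.ndarray  # (N, N) binary, symmetric, zero diagonal
    rejected: list[str]
    tau: float
    edge_scores: list[EdgeScore] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def class_names(self) -> list[str]:
        return sorted({l for l in self.labels if l is not None})

    def to_edgelist(self) -> list[tuple[str, str]]:
        """Undirected edges as (seq_a, seq_b) pairs, each reported once."""
        n = len(self.node_ids)
        return [
            (self.node_ids[i], self.node_ids[j])
            for i in range(n)
            for j in range(i + 1, n)
            if self.adjacency[i, j]
        ]


def build_knowledge_graph(
    features: Mapping[str, np.ndarray],
    labels: Mapping[str, str],
    edge_scores: Sequence[EdgeScore],
    tau: float = 1.0,
) -> KnowledgeGraph:
    """Assemble the binary knowledge graph from per-pair edge scores.

    ``features`` maps every sequence id to its node feature vector;
    ``labels`` maps reference ids to their family (query contigs are the
    ids absent from ``labels``).  An edge exists iff
    ``P_weight + E_weight > tau`` (strict).  Unlabeled nodes with no path
    to a labeled node are rejected and excluded from the returned graph.
    """
    ids = sorted(features)
    dims = {np.asarray(v).shape for v in features.values()}
    if len(dims) > 1:
        raise ValueError(f"inconsistent feature dimensions: {sorted(dims)}")
    g = nx.Graph()
    g.add_nodes_from(ids)
    for sc in edge_scores:
        if sc.seq_a not in features or sc.seq_b not in features:
            raise ValueError(f"edge endpoint without node feature: {sc.seq_a}/{sc.seq_b}")
        if sc.p_weight + sc.e_weight > tau:
            g.add_edge(sc.seq_a, sc.seq_b)

    rejected = []
    for comp in nx.connected_components(g):
        if not any(v in labels for v in comp):
            rejected.extend(v for v in comp if v not in labels)
    rejected_set = set(rejected)
    keep = [v for v in ids if v not in rejected_set]

    feats = np.stack([np.asarray(features[v], dtype=np.float64) for v in keep]) if keep else np.zeros((0, 0))
    adj = np.zeros((len(keep), len(keep)), dtype=np.float64)
    pos = {v: i for i, v in enumerate(keep)}
    for u, v in g.edges():
        if u in pos and v in pos:
            adj[pos[u], pos[v]] = 1.0
            adj[pos[v], pos[u]] = 1.0
    return KnowledgeGraph(
        node_ids=keep,
        features=feats,
        labels=[labels.get(v) for v in keep],
        adjacency=adj,
        rejected=sorted(rejected),
        tau=tau,
        edge_scores=list(edge_scores),
    )
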