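"""Directed information-source graphs with fixed in-degree.

Every agent observes exactly ``k`` distinct other agents — its information
pool ``G(i)``.  An edge j -> i exists iff j is a source of i, so edges point
in the direction of information flow.  In-degree is fixed at ``k`` for all
agents at all times (rewiring swaps a source, never adds or removes one), so
the edge count is always ``m = n * k``, while out-degrees are free: for the
random initializer they are approximately Binomial(n - 1, k/(n - 1)), as in
an Erdos-Renyi digraph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

TOPOLOGIES = ("random", "regular", "scale_free")

#: A category partition is a per-agent label vector (length n). Opinion
#: dichotomies use booleans: True/False for binary opinions, above/below the
#: true state for continuous ones (see :func:`echochamber.measures.dichotomize`).
CategoryPartition = np.ndarray


@dataclass
class SourceGraph:
    """Per-agent source sets stored as an ``(n, k)`` integer array.

    ``sources[i]`` lists the ``k`` distinct agents whose opinions agent i
    observes.  Invariants: no self-sources, no duplicates, every row has
    exactly ``k`` entries.
    """

    n: int
    k: int
    sources: np.ndarray
    topology: str = "random"

    @property
    def m(self) -> int:
        """Total number of edges, ``n * k``."""
        return self.n * self.k

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (source, recipient) index arrays of all m edges."""
        return self.sources.ravel(), np.repeat(np.arange(self.n), self.k)

    def validate(self) -> None:
        if self.sources.shape != (self.n, self.k):
            raise ValueError("sources array has the wrong shape")
        if (self.sources < 0).any() or (self.sources >= self.n).any():
            raise ValueError("source index out of range")
        for i in range(self.n):
            row = self.sources[i]
            if i in row:
                raise ValueError(f"agent {i} lists itself as a source")
            if len(set(row.tolist())) != self.k:
                raise ValueError(f"agent {i} has duplicate sources")

    def copy(self) -> "SourceGraph":
        return SourceGraph(self.n, self.k, self.sources.copy(), self.topology)

    def to_edgelist(self, path) -> None:
        """Write one 'source recipient' pair per line (plain text)."""
        src, rec = self.edge_arrays()
        with open(path, "w") as fh:
            for s, r in zip(src.tolist(), rec.tolist()):
                fh.write(f"{s} {r}\n")


def init_sources(
    n: int,
    k: int,
    topology: str = "random",
    rng: np.random.Generator | None = None,
) -> SourceGraph:
    """Initialize a fixed-in-degree source graph.

    ``random``
        Each agent's k sources drawn uniformly without replacement from the
        other n - 1 agents, independently of opinions.
    ``regular``
        Deterministic directed circulant: the sources of agent i are agents
        i-1, ..., i-k (mod n); every agent has in- and out-degree k.
    ``scale_free``
        In-degree fixed at k; sources chosen by preferential attachment on
        current out-degree + 1, producing a heavy-tailed out-degree
        distribution (a documented stand-in for alternative initial
        topologies; the directionally constrained analogue of
        Barabasi-Albert growth).
    """
    if not 1 <= k <= n - 1:
        raise ValueError(f"need 1 <= k <= n - 1, got n={n}, k={k}")
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")

    sources = np.empty((n, k), dtype=np.int64)

    if topology == "regular":
        for i in range(n):
            sources[i] = [(i - 1 - t) % n for t in range(k)]
        return SourceGraph(n, k, sources, topology)

    if rng is None:
        raise ValueError(f"{topology!r} initialization requires an rng")

    if topology == "random":
        for i in range(n):
            # draw from {0..n-2}, then shift indices >= i past the self slot
            choice = rng.choice(n - 1, size=k, replace=False)
            choice[choice >= i] += 1
            sources[i] = choice
        return SourceGraph(n, k, sources, topology)

    # scale_free: weight recipients' chosen sources by out-degree + 1
    weight = np.ones(n)
    for i in rng.permutation(n):
        w = weight.copy()
        w[i] = 0.0
        for slot in range(k):
            p = w / w.sum()
            j = int(rng.choice(n, p=p))
            sources[i, slot] = j
            w[j] = 0.0
        weight[sources[i]] += 1.0
    return SourceGraph(n, k, sources, topology)


def giant_scc_fraction(g: "SourceGraph | tuple") -> float:
    """Fraction of agents in the largest strongly connected component.

    Edges are interpreted source -> recipient; singleton components count as
    size 1, so the result lies in [1/n, 1].  Accepts either a
    :class:`SourceGraph` or a raw ``(n, sources, recipients)`` edge-array
    triple (the latter permits arbitrary digraphs, e.g. for comparisons
    against reachability oracles).
    """
    if isinstance(g, SourceGraph):
        n = g.n
        src, rec = g.edge_arrays()
    else:
        n, src, rec = g
        src = np.asarray(src, dtype=np.int64)
        rec = np.asarray(rec, dtype=np.int64)
    data = np.ones(len(src), dtype=np.int8)
    adj = csr_matrix((data, (src, rec)), shape=(n, n))
    _, labels = connected_components(adj, directed=True, connection="strong")
    counts = np.bincount(labels, minlength=n)
    return float(max(counts.max(), 1)) / n


def modularity(
    g: SourceGraph,
    partition: CategoryPartition,
    variant: str = "newman_directed",
) -> float:
    """Partition quality of the source graph over opinion categories.

    ``newman_directed`` is the standard directed modularity
    sum_d [ L_d/m - (k_d_in * k_d_out) / m^2 ], bounded in [-1, 1].

    ``squared`` is a nonstandard variant,
    sum_d [ L_d/m - (k_d_in * k_d_out / (2m))^2 ], which squares the
    degree-product null term and keeps the undirected 2m normalization on a
    directed degree product; it is *not* bounded in [-1, 1].  It is
    computed alongside the standard form so results remain comparable with
    fragmentation analyses that define Q this way.
    """
    labels = np.asarray(partition)
    if labels.shape != (g.n,):
        raise ValueError("partition must label every agent exactly once")
    if variant not in ("squared", "newman_directed"):
        raise ValueError(f"unknown modularity variant {variant!r}")

    m = g.m
    src, rec = g.edge_arrays()
    q = 0.0
    for d in np.unique(labels):
        in_d = labels == d
        l_d = int(np.count_nonzero(in_d[src] & in_d[rec]))
        k_in = g.k * int(np.count_nonzero(in_d))  # in-degree is k everywhere
        k_out = int(np.count_nonzero(in_d[src]))
        if variant == "squared":
            q += l_d / m - (k_in * k_out / (2.0 * m)) ** 2
        else:
            q += l_d / m - (k_in * k_out) / m**2
    return q
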