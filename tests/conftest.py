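"""Shared fixtures and small oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from echochamber import (
    SimulationState,
    SourceGraph,
    initialize_state,
    make_model_spec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_state(model="galton", n=None, k=5, beta=0.0, seed=0, topology="random"):
    """Freshly initialized simulation state with sensible small defaults."""
    spec = make_model_spec(model, {"n": n} if n is not None else None)
    return initialize_state(spec, k, beta, topology, np.random.default_rng(seed))


def make_custom_state(opinions, sources, model="galton", beta=0.0, seed=0):
    """State with hand-set opinions and sources (for worked examples).

    The model spec only supplies n, the opinion kind, and the good-decision
    band; opinions need not be draws from its distribution.
    """
    opinions = np.asarray(opinions, dtype=np.float64)
    sources = np.asarray(sources, dtype=np.int64)
    n, k = sources.shape
    assert opinions.shape == (n,)
    spec = make_model_spec(model, {"n": n})
    graph = SourceGraph(n=n, k=k, sources=sources)
    graph.validate()
    return SimulationState(
        spec=spec,
        graph=graph,
        opinions=opinions,
        beta=beta,
        rng=np.random.default_rng(seed),
    )


def sources_with_row0(n: int, k: int, row0) -> list:
    """Valid source table whose first row is ``row0``; filler rows for the rest."""
    rows = [list(row0)]
    for i in range(1, n):
        rows.append([j for j in range(n) if j != i][:k])
    return rows


def brute_force_scc_fraction(n: int, src, rec) -> float:
    """Largest-SCC fraction by boolean transitive closure (oracle, n small)."""
    reach = np.eye(n, dtype=bool)
    adj = np.zeros((n, n), dtype=bool)
    for s, r in zip(src, rec):
        adj[s, r] = True
    for _ in range(n):
        new = reach | (reach @ adj)
        if (new == reach).all():
            break
        reach = new
    mutual = reach & reach.T
    best = max(int(mutual[i].sum()) for i in range(n))
    return best / n
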