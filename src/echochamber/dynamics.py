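"""Round-based opinion/network dynamics and the simulation driver.

Each round draws a fresh uniform permutation of the agents; agents act
sequentially in that order, each seeing all updates made earlier in the same
round.  An acting agent draws *selective exposure* with probability beta and
*naive learning* with probability 1 - beta:

naive learning
    Adopt the opinion minimizing the summed absolute deviation from the
    agent's sources — their median (equivalently, the majority for binary
    opinions with odd k).

selective exposure
    Drop the source whose opinion differs most from the agent's own (ties
    broken uniformly at random) and connect instead to a uniformly chosen
    non-source whose opinion is *strictly* closer than the dropped one.  If
    the worst source agrees exactly, or no strictly closer non-source
    exists, nothing happens.  Opinions never change under this action.

A state is steady when every action drawable with nonzero probability is a
no-op for every agent, under every tie-breaking — the only reading of
"no further change occurs" that is robust to random tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import SourceGraph, init_sources
from .opinion_models import OpinionModelSpec, aggregate, sample_initial_opinions

logger = logging.getLogger(__name__)


@dataclass
class SimulationState:
    """Mutable simulation state: opinions + source graph + round counter."""

    spec: OpinionModelSpec
    graph: SourceGraph
    opinions: np.ndarray
    beta: float
    rng: np.random.Generator
    round: int = 0


@dataclass
class SteadyStateResult:
    """Outcome of one simulation run.

    ``rounds_to_steady`` is the index of the last round in which anything
    changed (the state is steady from the end of that round on);
    ``converged`` is False iff the round cap was hit first.  ``trajectory``
    holds one measure record per round boundary (round 0 = initial state)
    when recording was requested.
    """

    final_state: SimulationState
    rounds_to_steady: int
    converged: bool
    trajectory: list | None = None


def initialize_state(
    spec: OpinionModelSpec,
    k: int,
    beta: float,
    topology: str = "random",
    rng: np.random.Generator | int | np.random.SeedSequence | None = None,
) -> SimulationState:
    """Draw initial opinions and a source graph; package them as a state."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    opinions = sample_initial_opinions(spec, rng)
    graph = init_sources(spec.n, k, topology, rng)
    return SimulationState(spec=spec, graph=graph, opinions=opinions, beta=beta, rng=rng)


def discrepancy(state: SimulationState, i: int) -> float:
    """Summed absolute deviation between agent i and its sources."""
    x = state.opinions
    if not 0 <= i < state.spec.n:
        raise IndexError(f"agent index {i} out of range")
    return float(np.abs(x[state.graph.sources[i]] - x[i]).sum())


def _source_median(x: np.ndarray, sources_i: np.ndarray) -> float:
    xs = np.sort(x[sources_i])
    k = xs.size
    if k % 2:
        return float(xs[k // 2])
    return float(0.5 * (xs[k // 2 - 1] + xs[k // 2]))


def _learn(x: np.ndarray, sources: np.ndarray, i: int) -> bool:
    med = _source_median(x, sources[i])
    if med == x[i]:
        return False
    x[i] = med
    return True


def _rewire(
    x: np.ndarray, sources: np.ndarray, i: int, rng: np.random.Generator
) -> bool:
    row = sources[i]
    d = np.abs(x[row] - x[i])
    dmax = d.max()
    if dmax == 0.0:
        return False
    ties = np.flatnonzero(d == dmax)
    slot = int(ties[rng.integers(ties.size)]) if ties.size > 1 else int(ties[0])
    dist = np.abs(x - x[i])
    closer = dist < dmax
    closer[row] = False
    closer[i] = False
    candidates = np.flatnonzero(closer)
    if candidates.size == 0:
        return False
    sources[i, slot] = candidates[rng.integers(candidates.size)]
    return True


def naive_learning_action(state: SimulationState, i: int) -> bool:
    """Set agent i's opinion to its source median; True iff it changed."""
    if not 0 <= i < state.spec.n:
        raise IndexError(f"agent index {i} out of range")
    return _learn(state.opinions, state.graph.sources, i)


def selective_exposure_action(state: SimulationState, i: int) -> bool:
    """Rewire agent i away from its most discrepant source; True iff rewired.

    Opinions are never modified.  The in-degree of i is conserved: the
    dropped edge is replaced one-for-one, or retained when no strictly more
    congruent non-source exists.
    """
    if not 0 <= i < state.spec.n:
        raise IndexError(f"agent index {i} out of range")
    return _rewire(state.opinions, state.graph.sources, i, state.rng)


def step_round(state: SimulationState) -> bool:
    """Advance the state one round; True iff any opinion or edge changed."""
    rng = state.rng
    n = state.spec.n
    beta = state.beta
    x = state.opinions
    sources = state.graph.sources
    order = rng.permutation(n)
    coins = rng.random(n)
    changed = False
    for pos in range(n):
        i = int(order[pos])
        if coins[pos] < beta:
            changed |= _rewire(x, sources, i, rng)
        else:
            changed |= _learn(x, sources, i)
    state.round += 1
    return changed


def is_steady(state: SimulationState) -> bool:
    """Whether every drawable action is a no-op for every agent.

    For beta < 1 each agent's opinion must equal its source median; for
    beta > 0 each agent's rewiring must be a no-op.  The rewiring no-op
    condition is tie-breaking independent because the distance threshold
    |x_i - x_j*| is the same for every maximizer j*.  Consumes no
    randomness.
    """
    x = state.opinions
    sources = state.graph.sources
    beta = state.beta
    n = state.spec.n
    for i in range(n):
        row = sources[i]
        if beta < 1.0 and _source_median(x, row) != x[i]:
            return False
        if beta > 0.0:
            d = np.abs(x[row] - x[i])
            dmax = d.max()
            if dmax > 0.0:
                dist = np.abs(x - x[i])
                closer = dist < dmax
                closer[row] = False
                closer[i] = False
                if closer.any():
                    return False
    return True


def run_simulation(
    spec: OpinionModelSpec,
    k: int = 5,
    beta: float = 0.0,
    topology: str = "random",
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    max_rounds: int = 1000,
    record_trajectory: bool = False,
) -> SteadyStateResult:
    """Run one simulation to steady state (or the round cap).

    Deterministic given all parameters and ``seed``: the same inputs yield a
    bit-identical result.  When ``record_trajectory`` is set, a
    :class:`~echochamber.measures.MeasureRecord` is stored at round 0 and
    after every executed round.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be at least 1")
    from .measures import summarize  # local import; measures needs no dynamics

    state = initialize_state(spec, k, beta, topology, seed)
    trajectory = [summarize(state)] if record_trajectory else None

    if is_steady(state):
        return SteadyStateResult(state, 0, True, trajectory)

    last_change = 0
    for _ in range(max_rounds):
        changed = step_round(state)
        if record_trajectory:
            trajectory.append(summarize(state))
        if changed:
            last_change = state.round
        elif is_steady(state):
            return SteadyStateResult(state, last_change, True, trajectory)

    logger.warning(
        "run hit the round cap (%d) before reaching a steady state "
        "(model=%s, beta=%.3f)", max_rounds, spec.name, beta,
    )
    return SteadyStateResult(state, state.round, False, trajectory)
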