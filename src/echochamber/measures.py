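"""Per-run summaries: performance, opinion diversity, group structure.

Individual performance p_i is the fraction of agents whose current opinion
is a good decision; collective performance P_G is the fraction of runs whose
aggregated decision is good.  Opinion diversity sigma_x is the *population*
standard deviation of opinions (the dispersion of the whole group, not a
sample estimate).  Structure is summarized by the giant-SCC fraction |C1|
and by modularity over the opinion dichotomy, in both the standard directed
Newman variant and the nonstandard squared variant.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .network import CategoryPartition, giant_scc_fraction, modularity
from .opinion_models import OpinionModelSpec, aggregate, is_good_decision

#: Fixed column order for tabular serialization.
RECORD_FIELDS = (
    "individual_performance",
    "collective_decision",
    "collective_good",
    "opinion_diversity",
    "giant_scc_fraction",
    "modularity_newman",
    "modularity_squared",
    "round",
)


@dataclass(frozen=True)
class MeasureRecord:
    """One flat row of steady-state (or per-round) summary measures."""

    individual_performance: float
    collective_decision: float | bool
    collective_good: bool
    opinion_diversity: float
    giant_scc_fraction: float
    modularity_newman: float
    modularity_squared: float
    round: int

    def to_dict(self) -> dict:
        return asdict(self)


def dichotomize(opinions: np.ndarray, spec: OpinionModelSpec) -> CategoryPartition:
    """Two-level opinion categories: True/False, or above/below the true state.

    Continuous ties (probability zero) go below.
    """
    if spec.opinion_kind == "binary":
        return opinions == 1.0
    return opinions > spec.true_state


def summarize(state) -> MeasureRecord:
    """Compute all summary measures for the current state of one run."""
    spec: OpinionModelSpec = state.spec
    x = state.opinions

    if spec.opinion_kind == "binary":
        good_each = x == 1.0
    else:
        good_each = np.abs(x - spec.true_state) < spec.good_band_halfwidth
    p_i = float(np.count_nonzero(good_each)) / spec.n

    decision = aggregate(x, spec.aggregation_rule)
    good = is_good_decision(decision, spec, level="collective")

    labels = dichotomize(x, spec)
    return MeasureRecord(
        individual_performance=p_i,
        collective_decision=decision,
        collective_good=good,
        opinion_diversity=float(np.std(x)),
        giant_scc_fraction=giant_scc_fraction(state.graph),
        modularity_newman=modularity(state.graph, labels, "newman_directed"),
        modularity_squared=modularity(state.graph, labels, "squared"),
        round=int(state.round),
    )


def collective_performance(records) -> float:
    """Fraction of records whose collective decision was good (P_G)."""
    records = list(records)
    if not records:
        raise ValueError("collective_performance of an empty record collection")
    return sum(bool(r.collective_good) for r in records) / len(records)
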