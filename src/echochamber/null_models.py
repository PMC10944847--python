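"""Closed-form no-influence baselines.

The null model is the distribution of collective decisions obtained by
aggregating fresh, independent initial opinions with no dynamics at all:
the exact Condorcet jury probability for the binary model, the CLT normal
for mean aggregation, and the sample-median asymptotic normal for median
aggregation.  Simulated steady-state performance is judged against these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from scipy.stats import binom, norm

from .opinion_models import OpinionModelSpec

#: P(|Z| < 2) for standard normal Z — the good-decision probability of any
#: continuous-model null, since the standardized null decision is N(0, 1).
TWO_SIGMA_COVERAGE = float(2.0 * norm.cdf(2.0) - 1.0)


@dataclass(frozen=True)
class NullSummary:
    """No-influence baseline for one model.

    ``distribution`` is the (mean, variance) of the null collective
    decision.  For continuous models the variance equals
    ``collective_se**2``; for the binary jury the decision is Bernoulli with
    success probability ``good_probability``, and ``collective_se`` is its
    standard deviation.
    """

    model: str
    true_state: float
    collective_se: float
    good_probability: float
    mean: float
    variance: float

    def to_dict(self) -> dict:
        return asdict(self)


def condorcet_group_probability(n: int, p: float) -> float:
    """Exact probability a majority of n independent p-competent voters is right.

    The binomial tail P(Y > n/2) with Y ~ Bin(n, p), summed exactly (no
    normal approximation); n must be odd so that no tie rule is needed.
    """
    if n < 1 or n % 2 == 0:
        raise ValueError(f"group size must be odd and positive, got {n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"competence p must lie in (0, 1), got {p}")
    return float(binom.sf(n // 2, n, p))


def median_asymptotic_variance(density_at_median: float, m: int) -> float:
    """Asymptotic variance of the median of n = 2m + 1 i.i.d. draws.

    1 / (8 f(median)^2 m), where f is the parent density.
    """
    if density_at_median <= 0:
        raise ValueError("density at the median must be positive")
    if m < 1:
        raise ValueError(f"m must be at least 1, got {m}")
    return 1.0 / (8.0 * density_at_median**2 * m)


def aggregation_null(spec: OpinionModelSpec) -> NullSummary:
    """No-influence baseline for a model spec.

    Continuous models: the null decision is Normal(true_state,
    collective_se^2) and is good with probability 2*Phi(2) - 1 ~ 0.954.
    Binary jury: good with the exact jury probability.
    """
    if spec.opinion_kind == "binary":
        p_g = condorcet_group_probability(spec.n, spec.params["p"])
        var = p_g * (1.0 - p_g)
        return NullSummary(
            model=spec.name,
            true_state=spec.true_state,
            collective_se=math.sqrt(var),
            good_probability=p_g,
            mean=p_g,
            variance=var,
        )
    se = spec.collective_se
    return NullSummary(
        model=spec.name,
        true_state=spec.true_state,
        collective_se=se,
        good_probability=TWO_SIGMA_COVERAGE,
        mean=spec.true_state,
        variance=se**2,
    )
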