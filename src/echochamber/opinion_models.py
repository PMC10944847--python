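"""Generative models of initial opinions and the good-decision criterion.

Four named models cover the classical collective-decision settings: a binary
jury (``condorcet``), a unimodal continuous crowd (``galton``), a polarized
two-peak crowd (``bimodal``), and a right-skewed crowd aggregated by the
median (``exponential``).  Each model fixes the distribution of initial
opinions, the true state of nature, the rule that aggregates individual
opinions into a collective decision, and the standardized band that defines
a "good" decision (within two standard errors of the true state; for the
binary jury, simply the correct alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np

MODEL_NAMES = ("condorcet", "galton", "bimodal", "exponential")

AGGREGATION_RULES = ("majority", "mean", "median")


@dataclass(frozen=True)
class OpinionModelSpec:
    """Fully resolved description of one opinion model.

    Derived fields (``true_state``, ``population_sd``, ``collective_se``)
    are computed from ``params`` by :func:`make_model_spec`; construct specs
    through that factory rather than directly.

    ``collective_se`` is the standard error of the aggregated decision under
    independence: sigma/sqrt(n) for mean aggregation, the sample-median
    asymptotic standard error for median aggregation, and ``None`` for the
    binary jury, whose good-decision criterion is categorical rather than a
    band.
    """

    name: str
    n: int
    opinion_kind: str  # "binary" or "continuous"
    params: Mapping[str, float]
    true_state: float
    aggregation_rule: str
    population_sd: float
    collective_se: float | None

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", MappingProxyType(dict(self.params)))

    @property
    def good_band_halfwidth(self) -> float:
        """Half-width of the good-decision band, ``2 * collective_se``."""
        if self.collective_se is None:
            raise ValueError(
                f"{self.name!r} uses a categorical good-decision criterion"
            )
        return 2.0 * self.collective_se


_DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "condorcet": {"n": 101, "p": 0.55},
    "galton": {"n": 100, "mu": 0.0, "sigma2": 1.0},
    "bimodal": {"n": 100, "q": 0.5, "mu_low": -2.0, "mu_high": 2.0, "sigma_j2": 1.0},
    "exponential": {"n": 101, "lam": 1.0},
}


def make_model_spec(
    name: str, overrides: Mapping[str, float] | None = None
) -> OpinionModelSpec:
    """Build a fully populated :class:`OpinionModelSpec` with defaults.

    Parameters
    ----------
    name
        One of ``"condorcet"``, ``"galton"``, ``"bimodal"``, ``"exponential"``.
    overrides
        Optional mapping overriding declared parameters (including ``n``).
        Derived quantities are recomputed from the final parameter values.

    Notes
    -----
    Defaults are the standard study conditions: a 101-member jury with
    individual competence p = 0.55; a standard-normal crowd of 100; a
    symmetric two-component normal mixture (means +/-2, unit component
    variance, total variance 5) of 100; and a unit-rate exponential crowd of
    101 aggregated by the median, with true state ln 2.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    params = dict(_DEFAULT_PARAMS[name])
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise ValueError(f"unknown parameters for {name!r}: {sorted(unknown)}")
        params.update({k: v for k, v in overrides.items()})

    n = int(params.pop("n"))
    if n <= 0:
        raise ValueError(f"group size must be positive, got {n}")

    if name == "condorcet":
        p = float(params["p"])
        if not 0.0 < p < 1.0:
            raise ValueError(f"competence p must lie in (0, 1), got {p}")
        if n % 2 == 0:
            raise ValueError("condorcet requires odd n (majority needs no tie rule)")
        return OpinionModelSpec(
            name=name,
            n=n,
            opinion_kind="binary",
            params={"p": p},
            true_state=1.0,
            aggregation_rule="majority",
            population_sd=math.sqrt(p * (1.0 - p)),
            collective_se=None,
        )

    if name == "galton":
        mu = float(params["mu"])
        sigma2 = float(params["sigma2"])
        if sigma2 <= 0:
            raise ValueError(f"variance must be positive, got {sigma2}")
        sd = math.sqrt(sigma2)
        return OpinionModelSpec(
            name=name,
            n=n,
            opinion_kind="continuous",
            params={"mu": mu, "sigma2": sigma2},
            true_state=mu,
            aggregation_rule="mean",
            population_sd=sd,
            collective_se=sd / math.sqrt(n),
        )

    if name == "bimodal":
        q = float(params["q"])
        mu_low, mu_high = float(params["mu_low"]), float(params["mu_high"])
        sigma_j2 = float(params["sigma_j2"])
        if not 0.0 < q < 1.0:
            raise ValueError(f"mixture weight q must lie in (0, 1), got {q}")
        if sigma_j2 <= 0:
            raise ValueError(f"component variance must be positive, got {sigma_j2}")
        # mixture mean and the law-of-total-variance identity
        mu = q * mu_high + (1.0 - q) * mu_low
        between = q * (mu_high - mu) ** 2 + (1.0 - q) * (mu_low - mu) ** 2
        within = q * sigma_j2 + (1.0 - q) * sigma_j2
        sigma2 = between + within
        sd = math.sqrt(sigma2)
        return OpinionModelSpec(
            name=name,
            n=n,
            opinion_kind="continuous",
            params={
                "q": q,
                "mu_low": mu_low,
                "mu_high": mu_high,
                "sigma_j2": sigma_j2,
            },
            true_state=mu,
            aggregation_rule="mean",
            population_sd=sd,
            collective_se=sd / math.sqrt(n),
        )

    # exponential
    lam = float(params["lam"])
    if lam <= 0:
        raise ValueError(f"rate lambda must be positive, got {lam}")
    if n % 2 == 0:
        raise ValueError("exponential requires odd n = 2m + 1 (median aggregation)")
    median = math.log(2.0) / lam
    # sample-median asymptotics: var = 1 / (8 f(median)^2 m), f(median) = lam/2
    m = (n - 1) // 2
    density_at_median = lam * 0.5
    se = math.sqrt(1.0 / (8.0 * density_at_median**2 * m))
    return OpinionModelSpec(
        name=name,
        n=n,
        opinion_kind="continuous",
        params={"lam": lam},
        true_state=median,
        aggregation_rule="median",
        population_sd=1.0 / lam,
        collective_se=se,
    )


def sample_initial_opinions(
    spec: OpinionModelSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``spec.n`` i.i.d. initial opinions.

    Binary opinions are encoded as floats in {1.0 = True, 0.0 = False}, so
    that the median of an odd number of binary opinions coincides with their
    majority and the learning rule is uniform across models.
    """
    n = spec.n
    if spec.name == "condorcet":
        return (rng.random(n) < spec.params["p"]).astype(np.float64)
    if spec.name == "galton":
        return rng.normal(spec.params["mu"], math.sqrt(spec.params["sigma2"]), n)
    if spec.name == "bimodal":
        mus = np.where(
            rng.random(n) < spec.params["q"],
            spec.params["mu_high"],
            spec.params["mu_low"],
        )
        return mus + rng.normal(0.0, math.sqrt(spec.params["sigma_j2"]), n)
    return rng.exponential(1.0 / spec.params["lam"], n)


def aggregate(opinions: np.ndarray, rule: str) -> float | bool:
    """Aggregate an opinion vector into a collective decision.

    ``majority`` requires binary opinions of odd length and returns ``True``
    iff strictly more than half are True. ``median`` of an even-length
    vector is the midpoint of the two central order statistics (any point
    between them minimizes total absolute deviation; the midpoint is the
    deterministic, symmetric choice).
    """
    opinions = np.asarray(opinions, dtype=np.float64)
    if opinions.size == 0:
        raise ValueError("cannot aggregate an empty opinion vector")
    if rule == "majority":
        if opinions.size % 2 == 0:
            raise ValueError("majority is undefined for even-length vectors")
        if not np.isin(opinions, (0.0, 1.0)).all():
            raise ValueError("majority requires binary opinions in {0, 1}")
        return bool(opinions.sum() * 2 > opinions.size)
    if rule == "mean":
        return float(opinions.mean())
    if rule == "median":
        return float(np.median(opinions))
    raise ValueError(f"unknown aggregation rule {rule!r}")


def is_good_decision(
    value: float | bool, spec: OpinionModelSpec, level: str = "collective"
) -> bool:
    """Whether a decision is "good" under the spec's standardized criterion.

    Continuous models: good iff ``|value - true_state| < 2 * collective_se``
    (strict inequality; the same band applies to individual and collective
    decisions). The binary jury: good iff the decision is True.
    """
    if level not in ("individual", "collective"):
        raise ValueError(f"unknown level {level!r}")
    if spec.opinion_kind == "binary":
        if not isinstance(value, (bool, np.bool_)) and value not in (0.0, 1.0):
            raise ValueError(f"expected a binary decision, got {value!r}")
        return bool(value)
    if isinstance(value, (bool, np.bool_)):
        raise ValueError("expected a real-valued decision for a continuous model")
    return abs(float(value) - spec.true_state) < spec.good_band_halfwidth
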