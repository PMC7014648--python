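"""Privacy criteria.

Three models gate the release of anonymized training data:

* **k-anonymity** — every equivalence class over the quasi-identifiers
  must contain at least ``k`` records, bounding the per-record
  re-identification risk by ``1/k``.
* **Sampling-based (ε, δ)-differential privacy** — Bernoulli random
  sampling with probability β, followed by data-independent
  generalization and suppression of every class smaller than a derived
  threshold ``k``, satisfies (ε, δ)-differential privacy.  The tight
  budget for sampling alone is ε = −ln(1 − β); the residual δ is a
  maximized binomial tail (:func:`delta_bound`).
* **Game-theoretic profitability** — a record is protected when a
  rational adversary's expected payoff from attacking it, gain divided
  by its class size minus the attempt cost, is non-positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binom

from .dataset import Partition
from .errors import InfeasibleError, ParameterError, UndefinedMetricError

__all__ = [
    "KAnonymity",
    "DPParameters",
    "GameParameters",
    "check_k_anonymity",
    "max_reidentification_risk",
    "beta_from_epsilon",
    "epsilon_from_beta",
    "delta_bound",
    "dp_parameters",
    "adversary_payoff",
    "check_profitability",
    "game_class_size_threshold",
]

K_CEILING = 10**5  # dp_parameters gives up beyond this class-size threshold


@dataclass(frozen=True)
class KAnonymity:
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")


@dataclass(frozen=True)
class DPParameters:
    """Derived parameter set of the sampling-based DP mechanism."""

    epsilon: float
    delta: float
    beta: float
    k: int
    search_budget: float = 0.0

    @property
    def anonymization_budget(self) -> float:
        """Portion of ε consumed by sampling + suppression (the rest, if
        any, pays for data-dependent scheme selection)."""
        return self.epsilon - self.search_budget

    @property
    def gamma(self) -> float:
        e = math.exp(self.anonymization_budget)
        return (e - 1 + self.beta) / e


@dataclass(frozen=True)
class GameParameters:
    """Economics of a re-identification attack.

    ``adversary_cost`` is the cost per attempt, ``publisher_benefit`` the
    benefit per published record, ``gain`` the adversary's gain (equal to
    the publisher's loss) per successful re-identification.
    """

    adversary_cost: float
    publisher_benefit: float
    gain: float

    def __post_init__(self) -> None:
        if min(self.adversary_cost, self.publisher_benefit, self.gain) < 0:
            raise ParameterError("game parameters must be non-negative")


def check_k_anonymity(p: Partition, k: int) -> bool:
    """True iff every equivalence class has size >= k (vacuously true for
    an empty partition)."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    return all(s >= k for s in p.sizes)


def max_reidentification_risk(p: Partition) -> float:
    """Maximum per-record re-identification risk, 1 / (min class size)."""
    if not p.classes:
        raise UndefinedMetricError("risk undefined: no unsuppressed records")
    return 1.0 / p.min_size


def beta_from_epsilon(epsilon: float) -> float:
    """Largest sampling probability admissible at budget ε (tight bound
    ε = −ln(1 − β))."""
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    return 1.0 - math.exp(-epsilon)


def epsilon_from_beta(beta: float) -> float:
    """Tight ε consumed by Bernoulli sampling with probability β."""
    if not 0 < beta < 1:
        raise ParameterError("beta must be in (0, 1)")
    return -math.log(1.0 - beta)


def _gamma(epsilon: float, beta: float) -> float:
    e = math.exp(epsilon)
    return (e - 1 + beta) / e


def delta_bound(k: int, beta: float, epsilon: float, tol: float = 1e-15) -> float:
    """Residual δ of the sampling mechanism at class-size threshold ``k``.

    δ = max over class sizes n >= n_m of  P[Binomial(n, β) > γ·n], with
    γ = (e^ε − 1 + β) / e^ε and n_m = ceil(k/γ) − 1.  The scan over n
    stops once a Chernoff bound on the tail is provably below the running
    maximum by ``tol``.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if not 0 < beta <= 1:
        raise ParameterError("beta must be in (0, 1]")
    if beta == 1.0:
        return 1.0
    # tolerance is relative: near beta = 1 the round-trip -ln(1-beta)
    # amplifies float error in 1-beta considerably
    if epsilon < epsilon_from_beta(beta) - 1e-6 * max(1.0, abs(epsilon)):
        raise ParameterError(
            f"epsilon={epsilon:g} below the sampling cost -ln(1-beta)={epsilon_from_beta(beta):g}"
        )
    g = _gamma(epsilon, beta)
    n_m = max(1, math.ceil(k / g) - 1)
    # Chernoff exponent for P[Bin(n, beta) > gamma*n]; gamma > beta holds
    # whenever epsilon >= -ln(1-beta), so the tail decays geometrically.
    gc = min(g, 1.0 - 1e-12)
    kl = gc * math.log(gc / beta) + (1 - gc) * math.log((1 - gc) / (1 - beta))
    best = 0.0
    n = n_m
    while True:
        # strictly more than gamma*n successes
        thresh = math.floor(g * n)
        term = float(binom.sf(thresh, n, beta))
        if term > best:
            best = term
        n += 1
        if math.exp(-kl * n) < max(best, 1.0) * tol and n > n_m + 1:
            break
        if n > 10**6:  # defensive; never reached for sane parameters
            break
    return best


def dp_parameters(
    epsilon: float, delta: float, search_budget: float = 0.0
) -> DPParameters:
    """Derive (β, k) for the sampling-based DP mechanism.

    β is the largest sampling probability the anonymization budget admits;
    k is the smallest class-size threshold whose δ bound is <= δ.
    """
    if not 0 < delta < 1:
        raise ParameterError("delta must be in (0, 1)")
    if not 0 <= search_budget < epsilon:
        raise ParameterError("search_budget must satisfy 0 <= budget < epsilon")
    eps_anon = epsilon - search_budget
    beta = beta_from_epsilon(eps_anon)
    # delta_bound is non-increasing in k: doubling search, then bisection
    lo, hi = 1, 1
    if delta_bound(1, beta, eps_anon) <= delta:
        return DPParameters(epsilon, delta, beta, 1, search_budget)
    while delta_bound(hi, beta, eps_anon) > delta:
        lo = hi
        hi *= 2
        if hi > K_CEILING:
            raise InfeasibleError(
                f"no class-size threshold k <= {K_CEILING} achieves delta <= {delta:g}"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if delta_bound(mid, beta, eps_anon) <= delta:
            hi = mid
        else:
            lo = mid
    return DPParameters(epsilon, delta, beta, hi, search_budget)


def adversary_payoff(g: GameParameters, class_size: int) -> float:
    """Expected payoff of attacking a record in a class of the given size:
    gain at uniform success probability 1/size, minus the attempt cost."""
    if class_size < 1:
        raise ParameterError("class_size must be >= 1")
    return g.gain / class_size - g.adversary_cost


def game_class_size_threshold(g: GameParameters) -> float:
    """Smallest class size at which attacking is non-profitable (may be
    ``inf`` when attempts are free but the gain is positive)."""
    if g.gain == 0:
        return 1
    if g.adversary_cost == 0:
        return math.inf
    return math.ceil(g.gain / g.adversary_cost)


def check_profitability(p: Partition, g: GameParameters) -> tuple[bool, float]:
    """'No-attack' decision: the release is safe iff attacking every class
    is non-profitable.  Also returns the publisher's payoff: benefit per
    published record minus the expected loss over records in profitable
    classes."""
    safe = True
    expected_loss = 0.0
    for s in p.sizes:
        if adversary_payoff(g, s) > 0:
            safe = False
            expected_loss += s * (g.gain / s)
    payoff = g.publisher_benefit * p.n_unsuppressed - expected_loss
    return safe, payoff
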