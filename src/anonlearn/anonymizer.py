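"""Full-domain generalization lattice search.

The anonymization process enumerates every combination of generalization
levels over the quasi-identifying attributes (one lattice node = one
:class:`GeneralizationScheme`), applies each candidate, suppresses
equivalence classes below the privacy criterion's effective class-size
threshold (up to a configurable limit), discards candidates that violate
the criterion, and returns the satisfying candidate with the smallest
classification-aware penalty.  Ties break toward less total
generalization, then lexicographically.  The search is exhaustive — no
predictive pruning — with per-level column transforms memoised, so
correctness is easy to audit against a brute-force re-evaluation.

Differential privacy runs a different pipeline: Bernoulli sampling with
the derived probability β, a generalization scheme that is either fixed
(data-independent) or drawn by the exponential mechanism over the
lattice, and unconditional suppression of classes smaller than the
derived threshold k.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import (
    AttributeConfig,
    Dataset,
    GeneralizationScheme,
    Partition,
    aggregate_attribute,
    apply_scheme,
    compute_partition,
    sample_records,
    suppress_small_classes,
)
from .errors import ConfigError, InfeasibleError, ParameterError, UndefinedMetricError
from .hierarchy import Hierarchy
from .privacy import (
    DPParameters,
    GameParameters,
    KAnonymity,
    check_k_anonymity,
    check_profitability,
    dp_parameters,
    game_class_size_threshold,
)
from .utility import DEFAULT_SCORE_SENSITIVITY, UtilityScore, dp_score, multi_target_score

__all__ = [
    "DifferentialPrivacy",
    "RiskProfile",
    "AnonymizationResult",
    "Anonymizer",
    "enumerate_lattice",
    "risk_profile",
    "anonymize",
    "anonymize_dp",
]

LATTICE_CEILING = 10**6


@dataclass(frozen=True)
class DifferentialPrivacy:
    """Request for sampling-based (ε, δ)-differential privacy.

    ``search_budget`` is the portion of ε reserved for data-dependent
    scheme selection via the exponential mechanism; 0 selects the
    data-independent mode, which requires a fixed scheme.
    """

    epsilon: float
    delta: float
    search_budget: float = 0.0


@dataclass(frozen=True)
class RiskProfile:
    """Distribution of per-record re-identification risk (1/class size)."""

    histogram: tuple[tuple[float, float], ...]  # (risk, fraction), risk ascending
    max_risk: float
    n_records: int

    @classmethod
    def from_partition(cls, p: Partition) -> "RiskProfile":
        if not p.classes:
            raise UndefinedMetricError("risk profile undefined: no unsuppressed records")
        n = p.n_unsuppressed
        counts: dict[float, int] = {}
        for s in p.sizes:
            counts[1.0 / s] = counts.get(1.0 / s, 0) + s
        hist = tuple(sorted((r, c / n) for r, c in counts.items()))
        return cls(histogram=hist, max_risk=max(r for r, _ in hist), n_records=n)

    def fraction_at_risk_at_most(self, t: float) -> float:
        """Cumulative form: fraction of records with risk <= t."""
        return sum(f for r, f in self.histogram if r <= t + 1e-12)

    def plot(self, ax=None, **kwargs):
        """Bar plot of the risk histogram (risk level vs fraction of records)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        risks = [r for r, _ in self.histogram]
        fracs = [f for _, f in self.histogram]
        ax.bar([f"{100 * r:.3g}%" for r in risks], fracs, **kwargs)
        ax.set_xlabel("re-identification risk")
        ax.set_ylabel("fraction of records")
        return ax


def risk_profile(p: Partition) -> RiskProfile:
    """Histogram of per-record risk levels over a partition."""
    return RiskProfile.from_partition(p)


@dataclass
class AnonymizationResult:
    """Outcome of an anonymization run: the chosen lattice node, the
    transformed dataset and everything needed to audit the release."""

    scheme: GeneralizationScheme
    output: Dataset
    partition: Partition
    suppressed_count: int
    utility: UtilityScore
    privacy: object
    privacy_echo: dict
    risk_before: RiskProfile
    risk_after: RiskProfile | None
    removed_attributes: list[str]
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def max_risk(self) -> float | None:
        return self.risk_after.max_risk if self.risk_after is not None else None

    def summary(self) -> str:
        lines = []
        lines.append("Anonymization result")
        lines.append("=" * 60)
        lines.append(f"records                  {self.output.n_records}")
        lines.append(f"suppressed records       {self.suppressed_count}")
        lines.append(f"chosen scheme            {self.scheme}")
        lines.append(f"removed attributes       {', '.join(self.removed_attributes) or '-'}")
        for key, val in self.privacy_echo.items():
            lines.append(f"{key:<24} {val}")
        lines.append(
            f"utility penalty          {self.utility.penalty_count} "
            f"(normalized {self.utility.normalized:.4f})"
        )
        if self.risk_after is not None:
            lines.append(f"max risk before          {100 * self.risk_before.max_risk:.4g}%")
            lines.append(f"max risk after           {100 * self.risk_after.max_risk:.4g}%")
        return "\n".join(lines)

    def to_metadata(self) -> dict:
        meta = {
            "scheme": self.scheme.as_dict(),
            "suppressed_count": self.suppressed_count,
            "removed_attributes": list(self.removed_attributes),
            "privacy": dict(self.privacy_echo),
            "utility": {
                "penalty_count": self.utility.penalty_count,
                "normalized": self.utility.normalized,
                "per_target": dict(self.utility.per_target),
            },
            "risk_before": [list(x) for x in self.risk_before.histogram],
            "risk_after": [list(x) for x in self.risk_after.histogram]
            if self.risk_after
            else None,
            "seed": self.seed,
        }
        meta.update(self.metadata)
        return meta


def enumerate_lattice(
    hierarchies: Mapping[str, Hierarchy],
    qi_order: Sequence[str],
    ceiling: int = LATTICE_CEILING,
) -> list[GeneralizationScheme]:
    """All level combinations, ordered by total level ascending and
    lexicographically (in quasi-identifier order) within ties."""
    maxima = []
    for a in qi_order:
        if a not in hierarchies:
            raise ConfigError(f"quasi-identifier {a!r} has no hierarchy")
        maxima.append(hierarchies[a].max_level)
    size = 1
    for m in maxima:
        size *= m + 1
    if size > ceiling:
        raise InfeasibleError(f"lattice has {size} nodes, exceeding ceiling {ceiling}")
    combos = sorted(
        itertools.product(*(range(m + 1) for m in maxima)),
        key=lambda c: (sum(c), c),
    )
    return [GeneralizationScheme(tuple(zip(qi_order, c))) for c in combos]


class _CodedLattice:
    """Integer-coded per-level column transforms for the fast search path."""

    def __init__(self, d: Dataset, config: AttributeConfig):
        self.qi = config.quasi_identifiers
        self.n = d.n_records
        self.codes: dict[str, list[np.ndarray]] = {}
        self.cards: dict[str, list[int]] = {}
        for a in self.qi:
            h = config.hierarchies.get(a)
            col = d.df[a]
            per_level_codes, per_level_cards = [], []
            max_level = h.max_level if h is not None else 0
            for lev in range(max_level + 1):
                if lev == 0:
                    vals = col
                else:
                    uniq = col.unique()
                    mapping = {v: h.generalize(v, lev) for v in uniq}
                    vals = col.map(mapping)
                c, u = pd.factorize(vals, sort=False)
                per_level_codes.append(c.astype(np.int64))
                per_level_cards.append(max(len(u), 1))
            self.codes[a] = per_level_codes
            self.cards[a] = per_level_cards
        self.target_codes: dict[str, tuple[np.ndarray, int]] = {}
        for t in config.targets:
            c, u = pd.factorize(d.df[t], sort=False)
            self.target_codes[t] = (c.astype(np.int64), max(len(u), 1))

    def class_ids(self, scheme: GeneralizationScheme) -> tuple[np.ndarray, np.ndarray]:
        """(class index per record, class sizes)."""
        combined = np.zeros(self.n, dtype=np.int64)
        for a, lev in scheme.levels:
            combined = combined * self.cards[a][lev] + self.codes[a][lev]
        _, inv = np.unique(combined, return_inverse=True)
        sizes = np.bincount(inv)
        return inv, sizes


def _evaluate_candidate(
    coded: _CodedLattice,
    scheme: GeneralizationScheme,
    threshold: float,
    limit: float,
    targets: Sequence[str],
) -> tuple[bool, int, int, float]:
    """Fast evaluation of one lattice node.

    Returns (feasible, penalty, suppressed_count, suppressed_fraction);
    ``feasible`` is False when the suppression limit would be exceeded.
    """
    inv, sizes = coded.class_ids(scheme)
    small = sizes < threshold  # classes to suppress (inf threshold: all)
    n_suppressed = int(sizes[small].sum())
    n = coded.n
    frac = n_suppressed / n if n else 0.0
    if n and frac > limit + 1e-12:
        return False, 0, n_suppressed, frac
    kept_mask = ~small[inv]
    penalty = n_suppressed * len(targets)
    kept_sizes = sizes.copy()
    kept_sizes[small] = 0
    for t in targets:
        tcodes, tcard = coded.target_codes[t]
        combo = inv * tcard + tcodes
        counts = np.bincount(combo[kept_mask], minlength=len(sizes) * tcard)
        counts = counts.reshape(len(sizes), tcard)
        majority = counts.max(axis=1)
        penalty += int((kept_sizes - majority).clip(min=0).sum())
    return True, penalty, n_suppressed, frac


class Anonymizer:
    """Privacy-preserving training-data generator.

    Parameters
    ----------
    dataset:
        Input records.
    config:
        Attribute roles, hierarchies and aggregation options.
    privacy:
        :class:`KAnonymity`, :class:`GameParameters` or
        :class:`DifferentialPrivacy`.
    suppression_limit:
        Maximum fraction of records that may be suppressed while searching
        for a satisfying scheme (ignored under differential privacy, whose
        mechanism suppresses unconditionally).
    fixed_scheme:
        Generalization scheme for the data-independent DP mode.
    seed:
        Seed for sampling and the exponential mechanism (DP only).

    ``fit()`` runs the search and returns an :class:`AnonymizationResult`.
    """

    def __init__(
        self,
        dataset: Dataset,
        config: AttributeConfig,
        privacy,
        *,
        suppression_limit: float = 1.0,
        lattice_ceiling: int = LATTICE_CEILING,
        fixed_scheme: GeneralizationScheme | None = None,
        score_sensitivity: float = DEFAULT_SCORE_SENSITIVITY,
        seed: int | None = None,
    ) -> None:
        config.validate_against(dataset)
        config.require_targets()
        if not 0 <= suppression_limit <= 1:
            raise ParameterError("suppression limit must be in [0, 1]")
        self.dataset = dataset
        self.config = config
        self.privacy = privacy
        self.suppression_limit = suppression_limit
        self.lattice_ceiling = lattice_ceiling
        self.fixed_scheme = fixed_scheme
        self.score_sensitivity = score_sensitivity
        self.seed = seed

    # -- public API ----------------------------------------------------
    def fit(self) -> AnonymizationResult:
        if isinstance(self.privacy, DifferentialPrivacy):
            return self._fit_dp()
        if isinstance(self.privacy, (KAnonymity, GameParameters)):
            return self._fit_search()
        raise ConfigError(f"unsupported privacy model {type(self.privacy).__name__}")

    # -- lattice search (k-anonymity / game-theoretic) ------------------
    def _threshold(self) -> float:
        if isinstance(self.privacy, KAnonymity):
            return self.privacy.k
        return game_class_size_threshold(self.privacy)

    def _fit_search(self) -> AnonymizationResult:
        d = self.dataset
        qi = self.config.quasi_identifiers
        targets = self.config.targets
        lattice = enumerate_lattice(self.config.hierarchies, qi, self.lattice_ceiling)
        coded = _CodedLattice(d, self.config)
        threshold = self._threshold()
        best: tuple[int, GeneralizationScheme] | None = None
        near_misses: list[tuple[float, GeneralizationScheme]] = []
        for scheme in lattice:
            ok, penalty, _, frac = _evaluate_candidate(
                coded, scheme, threshold, self.suppression_limit, targets
            )
            if not ok:
                near_misses.append((frac, scheme))
                continue
            if best is None or penalty < best[0]:
                best = (penalty, scheme)
        if best is None:
            near_misses.sort(key=lambda x: x[0])
            closest = ", ".join(
                f"{s} (would suppress {100 * f:.1f}%)" for f, s in near_misses[:3]
            )
            raise InfeasibleError(
                f"no generalization scheme satisfies the criterion within the "
                f"suppression limit {self.suppression_limit:.0%}; closest: {closest}"
            )
        return self._materialize(best[1], threshold, suppression_limit=self.suppression_limit)

    # -- differential privacy -------------------------------------------
    def _fit_dp(self) -> AnonymizationResult:
        req: DifferentialPrivacy = self.privacy
        params = dp_parameters(req.epsilon, req.delta, req.search_budget)
        if self.seed is None:
            raise ConfigError("differential privacy requires a seed")
        rng = np.random.default_rng(self.seed)
        sample_seed = int(rng.integers(0, 2**31 - 1))
        sampled = sample_records(self.dataset, params.beta, sample_seed)
        if req.search_budget == 0.0:
            if self.fixed_scheme is None:
                raise ConfigError(
                    "data-independent differential privacy requires a fixed scheme"
                )
            scheme = self.fixed_scheme
        else:
            scheme = self._exponential_mechanism(sampled, params, rng)
        return self._materialize(
            scheme,
            params.k,
            suppression_limit=1.0,
            data=sampled,
            params=params,
            seed=self.seed,
            extra_meta={"sample_seed": sample_seed},
        )

    def _exponential_mechanism(
        self, d: Dataset, params: DPParameters, rng: np.random.Generator
    ) -> GeneralizationScheme:
        qi = self.config.quasi_identifiers
        lattice = enumerate_lattice(self.config.hierarchies, qi, self.lattice_ceiling)
        scores = np.array(
            [
                dp_score(
                    d,
                    s,
                    self.config.hierarchies,
                    qi,
                    self.config.targets,
                    k=params.k,
                    sensitivity=self.score_sensitivity,
                )
                for s in lattice
            ]
        )
        # log-space weights eps*score/(2*sensitivity); Gumbel-max draw
        logw = params.search_budget * scores / (2.0 * self.score_sensitivity)
        gumbel = rng.gumbel(size=len(logw))
        return lattice[int(np.argmax(logw + gumbel))]

    # -- shared materialization -----------------------------------------
    def _materialize(
        self,
        scheme: GeneralizationScheme,
        threshold: float,
        suppression_limit: float,
        data: Dataset | None = None,
        params: DPParameters | None = None,
        seed: int | None = None,
        extra_meta: dict | None = None,
    ) -> AnonymizationResult:
        d = data if data is not None else self.dataset
        qi = self.config.quasi_identifiers
        targets = self.config.targets
        risk_before = RiskProfile.from_partition(compute_partition(d, qi))
        transformed = apply_scheme(d, scheme, self.config.hierarchies)
        p = compute_partition(transformed, qi)
        k_eff = int(threshold) if math.isfinite(threshold) else d.n_records + 1
        transformed, p = suppress_small_classes(transformed, p, k_eff, suppression_limit)
        for a in sorted(self.config.aggregate):
            transformed = aggregate_attribute(
                transformed, p, a, self.config.aggregate_statistic
            )
        utility = multi_target_score(transformed, p, targets)
        risk_after = RiskProfile.from_partition(p) if p.classes else None
        removed = self._removed_attributes(transformed, p, scheme)
        echo = self._privacy_echo(params)
        result = AnonymizationResult(
            scheme=scheme,
            output=transformed,
            partition=p,
            suppressed_count=len(p.suppressed),
            utility=utility,
            privacy=self.privacy,
            privacy_echo=echo,
            risk_before=risk_before,
            risk_after=risk_after,
            removed_attributes=removed,
            seed=seed,
            metadata=dict(extra_meta or {}),
        )
        self._verify(result, params)
        return result

    def _removed_attributes(
        self, transformed: Dataset, p: Partition, scheme: GeneralizationScheme
    ) -> list[str]:
        removed = []
        unsup = np.flatnonzero(~transformed.suppressed)
        for a, lev in scheme.levels:
            h = self.config.hierarchies.get(a)
            if h is None or lev != h.max_level:
                continue
            if len(unsup) == 0 or transformed.df[a].iloc[unsup].nunique() <= 1:
                removed.append(a)
        return removed

    def _privacy_echo(self, params: DPParameters | None) -> dict:
        if isinstance(self.privacy, KAnonymity):
            return {"model": "k-anonymity", "k": self.privacy.k}
        if isinstance(self.privacy, GameParameters):
            g = self.privacy
            return {
                "model": "profitability (no-attack)",
                "adversary_cost": g.adversary_cost,
                "publisher_benefit": g.publisher_benefit,
                "gain": g.gain,
                "class_size_threshold": game_class_size_threshold(g),
            }
        assert params is not None
        return {
            "model": "(epsilon,delta)-differential privacy",
            "epsilon": params.epsilon,
            "delta": params.delta,
            "beta": params.beta,
            "k": params.k,
            "gamma": params.gamma,
            "search_budget": params.search_budget,
        }

    def _verify(self, result: AnonymizationResult, params: DPParameters | None) -> None:
        """Re-check the criterion on the materialized output."""
        p = result.partition
        if isinstance(self.privacy, KAnonymity):
            assert check_k_anonymity(p, self.privacy.k)
        elif isinstance(self.privacy, GameParameters):
            safe, payoff = check_profitability(p, self.privacy)
            assert safe
            result.privacy_echo["publisher_payoff"] = payoff
        elif params is not None:
            assert check_k_anonymity(p, params.k)


def anonymize(
    dataset: Dataset,
    config: AttributeConfig,
    privacy,
    suppression_limit: float = 1.0,
    **kwargs,
) -> AnonymizationResult:
    """Run the lattice search under k-anonymity or the game-theoretic
    criterion and return the optimal release."""
    return Anonymizer(
        dataset, config, privacy, suppression_limit=suppression_limit, **kwargs
    ).fit()


def anonymize_dp(
    dataset: Dataset,
    config: AttributeConfig,
    epsilon: float,
    delta: float,
    seed: int,
    search_budget: float = 0.0,
    fixed_scheme: GeneralizationScheme | None = None,
    **kwargs,
) -> AnonymizationResult:
    """Run the sampling-based differentially private release."""
    return Anonymizer(
        dataset,
        config,
        DifferentialPrivacy(epsilon, delta, search_budget),
        fixed_scheme=fixed_scheme,
        seed=seed,
        **kwargs,
    ).fit()
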