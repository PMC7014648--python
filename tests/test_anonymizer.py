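"""Lattice search, DP mechanism and risk profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from anonlearn import (
    AttributeConfig,
    Dataset,
    GameParameters,
    GeneralizationScheme,
    Hierarchy,
    KAnonymity,
    anonymize,
    anonymize_dp,
    apply_scheme,
    check_k_anonymity,
    compute_partition,
    enumerate_lattice,
    multi_target_score,
    risk_profile,
    suppress_small_classes,
)
from anonlearn.anonymizer import Anonymizer, DifferentialPrivacy
from anonlearn.errors import ConfigError, InfeasibleError


def brute_force_search(d, config, k, limit):
    """Independent exhaustive evaluation of every lattice node using only
    the public reference operations; returns (scheme, penalty) or None."""
    qi = config.quasi_identifiers
    best = None
    maxima = [config.hierarchies[a].max_level for a in qi]
    combos = sorted(
        itertools.product(*(range(m + 1) for m in maxima)), key=lambda c: (sum(c), c)
    )
    for combo in combos:
        scheme = GeneralizationScheme(tuple(zip(qi, combo)))
        out = apply_scheme(d, scheme, config.hierarchies)
        p = compute_partition(out, qi)
        try:
            out, p = suppress_small_classes(out, p, k, limit)
        except InfeasibleError:
            continue
        if not check_k_anonymity(p, k):
            continue
        pen = multi_target_score(out, p, config.targets).penalty_count
        if best is None or pen < best[1]:
            best = (scheme, pen)
    return best


def random_fixture(rng):
    n = int(rng.integers(20, 120))
    h_a = Hierarchy("a", [[v, "g" + v[0], "*"] for v in ["a1", "a2", "b1", "b2"]])
    h_b = Hierarchy("b", [["x", "*"], ["y", "*"], ["z", "*"]])
    h_c = Hierarchy(
        "c", [[str(i), f"p{i // 2}", f"q{i // 4}", "*"] for i in range(8)]
    )
    df = pd.DataFrame(
        {
            "a": rng.choice(["a1", "a2", "b1", "b2"], n),
            "b": rng.choice(["x", "y", "z"], n),
            "c": rng.choice([str(i) for i in range(8)], n),
            "t": rng.choice(["pos", "neg"], n, p=[0.4, 0.6]),
        }
    )
    config = AttributeConfig(
        roles={"a": "quasi_identifying_feature", "b": "quasi_identifying_feature",
               "c": "quasi_identifying_feature", "t": "target"},
        hierarchies={"a": h_a, "b": h_b, "c": h_c},
    )
    return Dataset(df, {}), config


class TestEnumerateLattice:
    def test_counts(self):
        h1 = Hierarchy("a", [["x", "*"], ["y", "*"]])
        h2 = Hierarchy("b", [["u", "g", "*"], ["v", "g", "*"], ["w", "h", "*"]])
        assert len(enumerate_lattice({"a": h1}, ["a"])) == 2
        assert len(enumerate_lattice({"a": h1, "b": h2}, ["a", "b"])) == 2 * 3
        h3 = Hierarchy("c", [["1", "p", "q", "*"]])
        assert len(enumerate_lattice({"b": h2, "c": h3}, ["b", "c"])) == 3 * 4

    def test_ordering(self):
        h1 = Hierarchy("a", [["x", "g", "*"]])
        h2 = Hierarchy("b", [["u", "*"]])
        lattice = enumerate_lattice({"a": h1, "b": h2}, ["a", "b"])
        assert lattice[0].as_dict() == {"a": 0, "b": 0}
        assert lattice[-1].as_dict() == {"a": 2, "b": 1}
        totals = [s.total for s in lattice]
        assert totals == sorted(totals)

    def test_ceiling(self):
        h = Hierarchy("a", [[str(i)] + [f"l{j}" for j in range(1, 10)] for i in range(2)])
        with pytest.raises(InfeasibleError, match="ceiling"):
            enumerate_lattice({"a": h, "b": h, "c": h}, ["a", "b", "c"], ceiling=100)


class TestLatticeSearch:
    def test_k1_returns_identity_scheme(self, toy_dataset, toy_config):
        res = anonymize(toy_dataset, toy_config, KAnonymity(1))
        assert res.scheme.as_dict() == {"age": 0, "sex": 0}
        assert res.suppressed_count == 0

    def test_k_equals_n_with_full_suppression_allowed(self, toy_dataset, toy_config):
        res = anonymize(toy_dataset, toy_config, KAnonymity(6))
        # a single class of all six records satisfies k=6 at the top scheme
        assert res.partition.sizes == [6]

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        for trial in range(20):
            d, config = random_fixture(rng)
            k = int(rng.integers(2, 6))
            limit = float(rng.choice([0.0, 0.2, 1.0]))
            expected = brute_force_search(d, config, k, limit)
            if expected is None:
                with pytest.raises(InfeasibleError):
                    anonymize(d, config, KAnonymity(k), suppression_limit=limit)
                continue
            res = anonymize(d, config, KAnonymity(k), suppression_limit=limit)
            assert res.utility.penalty_count == expected[1]
            assert res.scheme == expected[0]

    def test_output_recheck_from_written_file(self, tmp_path, toy_dataset, toy_config):
        from anonlearn import load_dataset, write_dataset

        res = anonymize(toy_dataset, toy_config, KAnonymity(2))
        p = tmp_path / "out.csv"
        write_dataset(res.output, p)
        reloaded = load_dataset(p)
        # starred rows are the suppressed ones; rebuild the partition
        sup = (reloaded.df == "*").all(axis=1).to_numpy()
        reloaded.suppressed[:] = sup
        part = compute_partition(reloaded, toy_config.quasi_identifiers)
        assert check_k_anonymity(part, 2)

    def test_penalty_monotone_in_k(self):
        rng = np.random.default_rng(22)
        d, config = random_fixture(rng)
        pens = []
        for k in range(2, 26):
            res = anonymize(d, config, KAnonymity(k))
            pens.append(res.utility.penalty_count)
        assert all(a <= b for a, b in zip(pens, pens[1:]))

    def test_dimensionality_reduction_removes_unique_attribute(self):
        # one attribute fully determines the target, another is unique per
        # record; at k=2 with no suppression allowed the unique attribute
        # must be generalized away while the predictive one is retained
        n = 40
        rng = np.random.default_rng(23)
        pred = rng.choice(["lo", "hi"], n)
        uid = [f"id{i}" for i in range(n)]
        df = pd.DataFrame({"pred": pred, "uid": uid,
                           "t": np.where(pred == "hi", "yes", "no")})
        config = AttributeConfig(
            roles={"pred": "quasi_identifying_feature",
                   "uid": "quasi_identifying_feature", "t": "target"},
            hierarchies={
                "pred": Hierarchy("pred", [["lo", "*"], ["hi", "*"]]),
                "uid": Hierarchy("uid", [[u, "*"] for u in uid]),
            },
        )
        res = anonymize(Dataset(df, {}), config, KAnonymity(2), suppression_limit=0.0)
        assert res.scheme.as_dict() == {"pred": 0, "uid": 1}
        assert res.removed_attributes == ["uid"]
        assert res.utility.penalty_count == 0

    def test_infeasible_reports_closest_candidates(self):
        df = pd.DataFrame({"q": ["a", "b"], "t": ["x", "y"]})
        config = AttributeConfig(
            roles={"q": "quasi_identifying_feature", "t": "target"},
            hierarchies={"q": Hierarchy("q", [["a", "a"], ["b", "b"]])},  # no merging
        )
        with pytest.raises(InfeasibleError, match="closest"):
            anonymize(Dataset(df, {}), config, KAnonymity(2), suppression_limit=0.0)


class TestGameTheoreticSearch:
    def test_threshold_behaviour(self):
        rng = np.random.default_rng(24)
        d, config = random_fixture(rng)
        g = GameParameters(adversary_cost=4.0, publisher_benefit=1200.0, gain=40.0)
        res = anonymize(d, config, g)
        # safe release: every remaining class at least ceil(40/4) = 10
        assert res.partition.min_size >= 10
        assert res.privacy_echo["publisher_payoff"] == pytest.approx(
            1200.0 * res.partition.n_unsuppressed
        )

    def test_zero_gain_keeps_everything(self):
        rng = np.random.default_rng(25)
        d, config = random_fixture(rng)
        g = GameParameters(adversary_cost=4.0, publisher_benefit=1.0, gain=0.0)
        res = anonymize(d, config, g)
        assert res.scheme.total == 0 and res.suppressed_count == 0


class TestDPMechanism:
    def _fixture(self):
        rng = np.random.default_rng(26)
        return random_fixture(rng)

    def test_data_independent_mode(self):
        d, config = self._fixture()
        eps = -np.log(0.4)
        fixed = GeneralizationScheme.from_dict({"a": 2, "b": 1, "c": 3})
        res = anonymize_dp(d, config, epsilon=eps, delta=0.22, seed=3, fixed_scheme=fixed)
        assert res.privacy_echo["k"] == 3
        assert res.privacy_echo["beta"] == pytest.approx(0.6)
        if res.risk_after is not None:
            assert res.risk_after.max_risk <= 1 / 3 + 1e-12


    def test_missing_fixed_scheme_rejected(self):
        d, config = self._fixture()
        with pytest.raises(ConfigError, match="fixed scheme"):
            anonymize_dp(d, config, epsilon=1.0, delta=1e-3, seed=1)

    def test_seeded_determinism(self):
        d, config = self._fixture()
        fixed = GeneralizationScheme.from_dict({"a": 2, "b": 1, "c": 3})
        r1 = anonymize_dp(d, config, epsilon=1.0, delta=1e-2, seed=11, fixed_scheme=fixed)
        r2 = anonymize_dp(d, config, epsilon=1.0, delta=1e-2, seed=11, fixed_scheme=fixed)
        assert r1.output == r2.output
        assert r1.scheme == r2.scheme

    def test_large_budget_approaches_identity(self):
        d, config = self._fixture()
        fixed = GeneralizationScheme.from_dict({"a": 0, "b": 0, "c": 0})
        res = anonymize_dp(d, config, epsilon=20.0, delta=1 - 1e-9, seed=5,
                           fixed_scheme=fixed)
        assert res.privacy_echo["k"] == 1
        # beta ~ 1: essentially every record survives untransformed
        assert res.output.n_records >= 0.95 * d.n_records

    def test_search_mode_concentrates_on_high_scores(self):
        # modal scheme over many seeds should have (near-)maximal score
        rng = np.random.default_rng(27)
        n = 60
        df = pd.DataFrame({
            "a": rng.choice(["a1", "a2", "b1", "b2"], n),
            "t": rng.choice(["x", "y"], n),
        })
        config = AttributeConfig(
            roles={"a": "quasi_identifying_feature", "t": "target"},
            hierarchies={"a": Hierarchy("a", [[v, "g" + v[0], "*"]
                                              for v in ["a1", "a2", "b1", "b2"]])},
        )
        d = Dataset(df, {})
        chosen = []
        for seed in range(300):
            res = anonymize_dp(d, config, epsilon=4.0, delta=0.5, seed=seed,
                               search_budget=3.0)
            chosen.append(tuple(sorted(res.scheme.as_dict().items())))
        modal = max(set(chosen), key=chosen.count)
        from anonlearn import dp_score
        from anonlearn.privacy import dp_parameters

        params = dp_parameters(4.0, 0.5, 3.0)
        lattice = enumerate_lattice(config.hierarchies, ["a"])
        scores = {
            tuple(sorted(s.as_dict().items())): dp_score(
                Dataset(df, {}), s, config.hierarchies, ["a"], ["t"], k=params.k
            )
            for s in lattice
        }
        assert scores[modal] == max(scores.values())


class TestRiskProfile:
    def test_all_singletons(self):
        df = pd.DataFrame({"q": ["a", "b", "c"]})
        p = compute_partition(Dataset(df, {}), ["q"])
        prof = risk_profile(p)
        assert prof.histogram == ((1.0, 1.0),)
        assert prof.max_risk == 1.0

    def test_mixed_class_sizes(self):
        df = pd.DataFrame({"q": ["a"] * 3 + ["b"] * 3 + ["c"] * 5})
        p = compute_partition(Dataset(df, {}), ["q"])
        prof = risk_profile(p)
        hist = dict(prof.histogram)
        assert hist[1 / 3] == pytest.approx(6 / 11)
        assert hist[1 / 5] == pytest.approx(5 / 11)
        assert prof.fraction_at_risk_at_most(1 / 5) == pytest.approx(5 / 11)
        assert prof.fraction_at_risk_at_most(1.0) == pytest.approx(1.0)

    def test_three_anonymous_release_risk_bounded(self, toy_dataset, toy_config):
        res = anonymize(toy_dataset, toy_config, KAnonymity(3))
        assert res.risk_after.max_risk <= 1 / 3 + 1e-12
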