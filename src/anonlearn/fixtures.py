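"""Deterministic synthetic data generators.

Every generator emulates the *shape and statistical structure* of a class
of small biomedical datasets — not any real dataset's values — so the
whole pipeline (hierarchies, anonymization, training, evaluation) can be
exercised without external downloads:

* :func:`make_inflammation_like` — binary symptoms plus a body
  temperature, with two diagnosis targets that are deterministic boolean
  rules over a few symptoms (optionally corrupted by symmetric label
  noise).  Mirrors expert-system style diagnosis data.
* :func:`make_cytopathology_like` — ordinal 1–10 cytology scores with a
  monotone, single-attribute-dominated malignancy relation and optional
  missing cells.
* :func:`make_contraceptive_like` — mixed demographic attributes with a
  3-class target drawn from a configured class mixture, features sampled
  conditionally on the class.
* :func:`make_fig2_style_fixture` — a fixed 5-record toy table with a
  data-independent transformation scheme, a 3-of-5 sampling step and
  3-anonymous post-suppression, whose release guarantees evaluate to
  max risk ≤ 1/3 and (ε, δ) ≈ (0.92, 0.22).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import AttributeConfig, Dataset, GeneralizationScheme
from .hierarchy import Hierarchy, IntervalSpec, build_interval_hierarchy
from .privacy import delta_bound, epsilon_from_beta

__all__ = [
    "FixtureBundle",
    "make_inflammation_like",
    "make_cytopathology_like",
    "make_contraceptive_like",
    "make_fig2_style_fixture",
    "make",
    "GENERATORS",
]


@dataclass
class FixtureBundle:
    """A dataset together with the hierarchies and attribute configuration
    needed to anonymize and evaluate it."""

    dataset: Dataset
    hierarchies: dict[str, Hierarchy]
    config: AttributeConfig
    metadata: dict = field(default_factory=dict)


def _binary_hierarchy(attribute: str) -> Hierarchy:
    return Hierarchy(attribute, [["yes", "*"], ["no", "*"]])


def _score_hierarchy(attribute: str, with_na: bool = False) -> Hierarchy:
    """Ordinal 1–10 hierarchy merging score ranges pairwise up to '*'."""
    rows = []
    for i in range(1, 11):
        pair = f"{((i - 1) // 2) * 2 + 1}-{((i - 1) // 2) * 2 + 2}"
        quad_lo = ((i - 1) // 4) * 4 + 1
        quad = f"{quad_lo}-{min(quad_lo + 3, 10)}" if quad_lo < 9 else "9-10"
        octv = "1-8" if i <= 8 else "9-10"
        rows.append([str(i), pair, quad, octv, "*"])
    if with_na:
        rows.append(["NA", "NA", "NA", "NA", "*"])
    return Hierarchy(attribute, rows)


def _ordinal4_hierarchy(attribute: str) -> Hierarchy:
    rows = [[str(i), "1-2" if i <= 2 else "3-4", "*"] for i in range(1, 5)]
    return Hierarchy(attribute, rows)


def _flip(rng: np.random.Generator, labels: np.ndarray, noise: float) -> np.ndarray:
    """Symmetric binary label noise."""
    if noise <= 0:
        return labels
    flip = rng.random(len(labels)) < noise
    out = labels.copy()
    out[flip] = np.where(labels[flip] == "yes", "no", "yes")
    return out


def make_inflammation_like(n: int = 120, seed: int = 0, noise: float = 0.0) -> FixtureBundle:
    """Acute-inflammation style fixture.

    One numeric temperature plus six binary symptoms; two binary diagnosis
    targets, each a deterministic rule over two or three features:
    ``bladder_inflammation`` = urine pushing AND micturition pains,
    ``nephritis`` = temperature >= 39 AND lumbar pain.  ``noise`` flips
    each target label independently with the given probability.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    rng = np.random.default_rng(seed)
    temp = np.round(rng.uniform(35.5, 42.5, size=n), 1)
    symptoms = ["nausea", "lumbar_pain", "urine_pushing", "micturition_pains",
                "urethral_burning", "chills"]
    cols = {"temperature": [f"{t:g}" for t in temp]}
    draws = {s: rng.random(n) < 0.5 for s in symptoms}
    for s in symptoms:
        cols[s] = np.where(draws[s], "yes", "no")
    bladder = np.where(draws["urine_pushing"] & draws["micturition_pains"], "yes", "no")
    nephritis = np.where((temp >= 39) & draws["lumbar_pain"], "yes", "no")
    cols["bladder_inflammation"] = _flip(rng, bladder, noise)
    cols["nephritis"] = _flip(rng, nephritis, noise)
    df = pd.DataFrame(cols)
    kinds = {a: "categorical" for a in df.columns}
    kinds["temperature"] = "numeric"
    # leaves at 0.1 resolution so that every emitted (0.1-rounded) value is
    # a table leaf and the hierarchy survives a write/load round trip
    hierarchies = {"temperature": build_interval_hierarchy(
        "temperature", IntervalSpec(cuts=(35.0, 37.0, 39.0, 41.0, 43.0), step=0.1)
    )}
    for s in symptoms:
        hierarchies[s] = _binary_hierarchy(s)
    roles = {a: "quasi_identifying_feature" for a in ["temperature", *symptoms]}
    roles["bladder_inflammation"] = "target"
    roles["nephritis"] = "target"
    config = AttributeConfig(roles=roles, hierarchies=hierarchies)
    return FixtureBundle(
        dataset=Dataset(df, kinds),
        hierarchies=hierarchies,
        config=config,
        metadata={"seed": seed, "noise": noise,
                  "rules": {"bladder_inflammation": "urine_pushing & micturition_pains",
                            "nephritis": "temperature>=39 & lumbar_pain"}},
    )


def make_cytopathology_like(
    n: int = 699,
    seed: int = 0,
    missing_rate: float = 0.0,
    dominant_weight: float = 1.5,
    other_weight: float = 0.05,
) -> FixtureBundle:
    """Cytopathology-score fixture: nine ordinal 1–10 features, a binary
    malignancy target with a monotone logistic dependence dominated by the
    first feature, and an optional missing-cell rate (missing cells become
    the category ``"NA"``)."""
    if n < 50:
        raise ValueError("n must be >= 50")
    rng = np.random.default_rng(seed)
    feats = [f"score_{i}" for i in range(1, 10)]
    X = rng.integers(1, 11, size=(n, 9)).astype(float)
    logit = dominant_weight * (X[:, 0] - 5.5) + other_weight * (X[:, 1:] - 5.5).sum(axis=1)
    y = np.where(rng.random(n) < 1.0 / (1.0 + np.exp(-logit)), "malignant", "benign")
    cols = {}
    for j, f in enumerate(feats):
        col = np.array([f"{int(v)}" for v in X[:, j]], dtype=object)
        if missing_rate > 0:
            col[rng.random(n) < missing_rate] = "NA"
        cols[f] = col
    cols["diagnosis"] = y
    df = pd.DataFrame(cols)
    hierarchies = {f: _score_hierarchy(f, with_na=True) for f in feats}
    roles = {f: "quasi_identifying_feature" for f in feats}
    roles["diagnosis"] = "target"
    config = AttributeConfig(roles=roles, hierarchies=hierarchies)
    return FixtureBundle(
        dataset=Dataset(df, {a: "categorical" for a in df.columns}),
        hierarchies=hierarchies,
        config=config,
        metadata={"seed": seed, "missing_rate": missing_rate,
                  "dominant_feature": "score_1", "dominant_weight": dominant_weight},
    )


def make_contraceptive_like(
    n: int = 1473,
    seed: int = 0,
    class_mix: tuple[float, float, float] = (0.43, 0.35, 0.22),
) -> FixtureBundle:
    """Demographic-survey fixture: mixed numeric/ordinal/binary attributes
    and a 3-class target (``none`` / ``short_term`` / ``long_term``) drawn
    from ``class_mix``; features are sampled conditionally on the class so
    the signal is recoverable but noisy."""
    if n < 100:
        raise ValueError("n must be >= 100")
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    rng = np.random.default_rng(seed)
    classes = np.array(["none", "short_term", "long_term"], dtype=object)
    y = classes[rng.choice(3, size=n, p=list(class_mix))]
    mu_age = {"none": 36.0, "short_term": 27.0, "long_term": 32.0}
    lam_child = {"none": 2.0, "short_term": 1.2, "long_term": 3.5}
    p_educ_hi = {"none": 0.35, "short_term": 0.65, "long_term": 0.5}
    age = np.clip(np.round(np.array([rng.normal(mu_age[c], 5.0) for c in y])), 16, 49)
    children = np.array([rng.poisson(lam_child[c]) for c in y]).clip(0, 11)
    educ = np.where(
        rng.random(n) < np.array([p_educ_hi[c] for c in y]),
        rng.integers(3, 5, size=n),
        rng.integers(1, 3, size=n),
    )
    df = pd.DataFrame({
        "age": [f"{a:g}" for a in age],
        "education": [str(e) for e in educ],
        "husband_education": [str(e) for e in rng.integers(1, 5, size=n)],
        "n_children": [f"{c:g}" for c in children],
        "religion": np.where(rng.random(n) < 0.85, "yes", "no"),
        "working": np.where(rng.random(n) < 0.25, "yes", "no"),
        "husband_occupation": [str(e) for e in rng.integers(1, 5, size=n)],
        "living_standard": [str(e) for e in rng.integers(1, 5, size=n)],
        "media_exposure": np.where(rng.random(n) < 0.92, "yes", "no"),
        "contraceptive_method": y,
    })
    kinds = {a: "categorical" for a in df.columns}
    kinds["age"] = "numeric"
    kinds["n_children"] = "numeric"
    hierarchies = {
        "age": build_interval_hierarchy(
            "age", IntervalSpec(cuts=(15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0))
        ),
        "n_children": build_interval_hierarchy(
            "n_children", IntervalSpec(cuts=(0.0, 2.0, 4.0, 12.0))
        ),
        "education": _ordinal4_hierarchy("education"),
        "husband_education": _ordinal4_hierarchy("husband_education"),
        "husband_occupation": _ordinal4_hierarchy("husband_occupation"),
        "living_standard": _ordinal4_hierarchy("living_standard"),
        "religion": _binary_hierarchy("religion"),
        "working": _binary_hierarchy("working"),
        "media_exposure": _binary_hierarchy("media_exposure"),
    }
    roles = {a: "quasi_identifying_feature" for a in df.columns}
    roles["contraceptive_method"] = "target"
    config = AttributeConfig(roles=roles, hierarchies=hierarchies)
    return FixtureBundle(
        dataset=Dataset(df, kinds),
        hierarchies=hierarchies,
        config=config,
        metadata={"seed": seed, "class_mix": list(class_mix)},
    )


# Seed for which Bernoulli(0.6) sampling keeps exactly records 1, 2 and 3
# of the 5-record toy table — part of the fixed fixture definition.
FIG2_SAMPLING_SEED = 0
FIG2_BETA = 0.6
FIG2_K = 3


def make_fig2_style_fixture() -> FixtureBundle:
    """Fixed worked-example fixture: five records, a data-independent
    scheme generalizing every quasi-identifier into one equivalence class,
    Bernoulli sampling that keeps three of the five records, and
    suppression of classes below size 3.

    The release guarantees are recomputable: maximum re-identification
    risk 1/3 (3-anonymity) and (ε, δ)-differential privacy with
    ε = −ln(1 − 0.6) ≈ 0.92 and δ = delta_bound(3, 0.6, ε) ≈ 0.22.
    """
    df = pd.DataFrame({
        "age": ["34", "45", "66", "70", "35"],
        "sex": ["male", "female", "male", "female", "female"],
        "zip": ["81667", "81675", "81925", "81931", "81669"],
        "disease": ["pneumonia", "gastritis", "gastritis", "pneumonia", "gastritis"],
    })
    kinds = {"age": "numeric", "sex": "categorical", "zip": "categorical",
             "disease": "categorical"}
    age_rows = [
        ["34", "30-39", "<50", "*"],
        ["45", "40-49", "<50", "*"],
        ["66", "60-69", ">=50", "*"],
        ["70", "70-79", ">=50", "*"],
        ["35", "30-39", "<50", "*"],
    ]
    zip_rows = [[z, z[:3] + "**", "*"] for z in df["zip"]]
    hierarchies = {
        "age": Hierarchy("age", age_rows),
        "sex": Hierarchy("sex", [["male", "*"], ["female", "*"]]),
        "zip": Hierarchy("zip", zip_rows),
    }
    roles = {"age": "quasi_identifying_feature", "sex": "quasi_identifying_feature",
             "zip": "quasi_identifying_feature", "disease": "target"}
    config = AttributeConfig(roles=roles, hierarchies=hierarchies)
    scheme = GeneralizationScheme.from_dict({"age": 3, "sex": 1, "zip": 2})
    epsilon = epsilon_from_beta(FIG2_BETA)
    delta = delta_bound(FIG2_K, FIG2_BETA, epsilon)
    return FixtureBundle(
        dataset=Dataset(df, kinds),
        hierarchies=hierarchies,
        config=config,
        metadata={
            "scheme": scheme,
            "beta": FIG2_BETA,
            "k": FIG2_K,
            "sampling_seed": FIG2_SAMPLING_SEED,
            "epsilon": epsilon,
            "delta": delta,
        },
    )


GENERATORS = {
    "inflammation": make_inflammation_like,
    "cytopathology": make_cytopathology_like,
    "contraceptive": make_contraceptive_like,
}


def make(generator: str, n: int, seed: int, **kwargs) -> FixtureBundle:
    """Dispatch by generator name (CLI entry point)."""
    if generator not in GENERATORS:
        raise ValueError(f"unknown generator {generator!r}; choose from {sorted(GENERATORS)}")
    return GENERATORS[generator](n=n, seed=seed, **kwargs)
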