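"""Run configuration: a YAML document naming attribute roles, hierarchy
sources, the privacy model and its parameters, transformation options and
classifier settings.

Example
-------
::

    attributes:
      - name: age
        kind: numeric
        role: quasi_identifying_feature
        interval: {cuts: [15, 20, 25, 30, 35, 40, 45, 50], merge_factor: 2}
      - name: sex
        kind: categorical
        role: quasi_identifying_feature
        hierarchy: sex.csv
      - name: diagnosis
        role: target
    privacy:
      model: k_anonymity
      k: 5
    transform:
      suppression_limit: 1.0
    classifier: {kind: random_forest, folds: 10}
    seed: 42
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .anonymizer import DifferentialPrivacy
from .dataset import AttributeConfig, GeneralizationScheme
from .errors import ConfigError
from .evaluation import ClassifierSpec
from .hierarchy import IntervalSpec, build_interval_hierarchy, load_hierarchy
from .privacy import GameParameters, KAnonymity

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    attribute_config: AttributeConfig
    kinds: dict[str, str]
    privacy: object
    suppression_limit: float = 1.0
    seed: int | None = None
    fixed_scheme: GeneralizationScheme | None = None
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    folds: int = 10
    delimiter: str = ","
    hierarchy_delimiter: str = ";"


def _privacy_from(doc: dict):
    model = doc.get("model")
    if model in ("k_anonymity", "k-anonymity"):
        return KAnonymity(k=int(doc["k"]))
    if model in ("differential_privacy", "dp"):
        return DifferentialPrivacy(
            epsilon=float(doc["epsilon"]),
            delta=float(doc["delta"]),
            search_budget=float(doc.get("search_budget", 0.0)),
        )
    if model in ("profitability", "game_theoretic", "game"):
        return GameParameters(
            adversary_cost=float(doc.get("adversary_cost", 4.0)),
            publisher_benefit=float(doc.get("publisher_benefit", 1200.0)),
            gain=float(doc.get("gain", 0.0)),
        )
    raise ConfigError(f"unknown privacy model {model!r}")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    base = os.path.dirname(os.path.abspath(path))
    hier_delim = doc.get("hierarchy_delimiter", ";")
    roles, kinds, hierarchies, aggregate = {}, {}, {}, set()
    for att in doc.get("attributes", []):
        name = att["name"]
        roles[name] = att.get("role", "quasi_identifying_feature")
        kinds[name] = att.get("kind", "categorical")
        if "hierarchy" in att:
            hpath = att["hierarchy"]
            if not os.path.isabs(hpath):
                hpath = os.path.join(base, hpath)
            hierarchies[name] = load_hierarchy(hpath, attribute=name, delimiter=hier_delim)
        elif "interval" in att:
            spec = att["interval"]
            hierarchies[name] = build_interval_hierarchy(
                name,
                IntervalSpec(
                    cuts=tuple(float(c) for c in spec["cuts"]),
                    merge_factor=int(spec.get("merge_factor", 2)),
                    step=float(spec.get("step", 1.0)),
                ),
            )
        if att.get("aggregate"):
            aggregate.add(name)
    attribute_config = AttributeConfig(
        roles=roles, hierarchies=hierarchies, aggregate=aggregate,
        aggregate_statistic=doc.get("transform", {}).get("aggregate_statistic", "mean"),
    )
    privacy = _privacy_from(doc.get("privacy", {}))
    transform = doc.get("transform", {}) or {}
    fixed_scheme = None
    if "fixed_scheme" in transform:
        fixed_scheme = GeneralizationScheme.from_dict(
            {a: int(l) for a, l in transform["fixed_scheme"].items()}
        )
    clf_doc = doc.get("classifier", {}) or {}
    classifier = ClassifierSpec(
        kind=clf_doc.get("kind", "logistic_regression"),
        regularization=float(clf_doc.get("regularization", 1.0)),
        n_trees=int(clf_doc.get("n_trees", 100)),
        max_depth=clf_doc.get("max_depth"),
        seed=int(clf_doc.get("seed", doc.get("seed", 0) or 0)),
    )
    return RunConfig(
        attribute_config=attribute_config,
        kinds=kinds,
        privacy=privacy,
        suppression_limit=float(transform.get("suppression_limit", 1.0)),
        seed=doc.get("seed"),
        fixed_scheme=fixed_scheme,
        classifier=classifier,
        folds=int(clf_doc.get("folds", 10)),
        delimiter=doc.get("delimiter", ","),
        hierarchy_delimiter=hier_delim,
    )
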