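import numpy as np
import pandas as pd
import pytest

from anonlearn import AttributeConfig, Dataset, Hierarchy


@pytest.fixture
def age_hierarchy() -> Hierarchy:
    """Small age hierarchy: exact -> decade -> half-century -> '*'."""
    rows = [
        ["34", "30-39", "<50", "*"],
        ["45", "40-49", "<50", "*"],
        ["35", "30-39", "<50", "*"],
        ["66", "60-69", ">=50", "*"],
        ["70", "70-79", ">=50", "*"],
        ["52", "50-59", ">=50", "*"],
    ]
    return Hierarchy("age", rows)


@pytest.fixture
def sex_hierarchy() -> Hierarchy:
    return Hierarchy("sex", [["male", "*"], ["female", "*"]])


@pytest.fixture
def toy_dataset() -> Dataset:
    df = pd.DataFrame(
        {
            "age": ["34", "45", "35", "66", "70", "52"],
            "sex": ["male", "female", "male", "male", "female", "female"],
            "disease": ["flu", "flu", "flu", "ulcer", "ulcer", "flu"],
        }
    )
    return Dataset(df, {"age": "numeric", "sex": "categorical", "disease": "categorical"})


@pytest.fixture
def toy_config(age_hierarchy, sex_hierarchy) -> AttributeConfig:
    return AttributeConfig(
        roles={
            "age": "quasi_identifying_feature",
            "sex": "quasi_identifying_feature",
            "disease": "target",
        },
        hierarchies={"age": age_hierarchy, "sex": sex_hierarchy},
    )


def brute_force_partition(values: list[tuple]) -> list[list[int]]:
    """Reference grouping by tuple equality, order of first appearance."""
    groups: dict[tuple, list[int]] = {}
    for i, v in enumerate(values):
        groups.setdefault(v, []).append(i)
    return list(groups.values())


def pairwise_auc(scores, labels) -> float:
    """Rank-statistic AUC: P(random positive outranks random negative),
    ties counted 1/2.  Quadratic; the independent oracle for ROC AUC."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))
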