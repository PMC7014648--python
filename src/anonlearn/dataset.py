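"""Tabular data model, attribute roles, equivalence classes and the
record-level transformation schemes (sampling, aggregation, suppression,
categorization, generalization).

A :class:`Dataset` stores every cell as text.  Numeric attributes are
validated to parse as numbers on load, but generalization may replace
them by interval labels, so text is the common representation throughout
the anonymization pipeline.  Record suppression is a flag: suppressed
rows are retained (and written fully starred) so record counts stay
auditable, but they are excluded from equivalence classes and from
classifier training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DatasetFormatError, InfeasibleError
from .hierarchy import Hierarchy

__all__ = [
    "SUPPRESSION_TOKEN",
    "Dataset",
    "AttributeConfig",
    "GeneralizationScheme",
    "Partition",
    "load_dataset",
    "write_dataset",
    "apply_scheme",
    "compute_partition",
    "suppress_small_classes",
    "sample_records",
    "aggregate_attribute",
    "suppress_cells",
]

SUPPRESSION_TOKEN = "*"

ROLES = ("quasi_identifying_feature", "target", "excluded")


class Dataset:
    """Rectangular table of text cells with declared attribute kinds."""

    def __init__(
        self,
        df: pd.DataFrame,
        kinds: Mapping[str, str],
        suppressed: np.ndarray | None = None,
    ) -> None:
        if df.columns.duplicated().any():
            raise DatasetFormatError("attribute names must be unique")
        self.df = df.astype(str)
        self.df.reset_index(drop=True, inplace=True)
        self.kinds = dict(kinds)
        for a in self.df.columns:
            self.kinds.setdefault(a, "categorical")
        n = len(self.df)
        if suppressed is None:
            suppressed = np.zeros(n, dtype=bool)
        self.suppressed = np.asarray(suppressed, dtype=bool).copy()
        if self.suppressed.shape != (n,):
            raise DatasetFormatError("suppressed flag length mismatch")

    @property
    def attributes(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_suppressed(self) -> int:
        return int(self.suppressed.sum())

    def copy(self) -> "Dataset":
        return Dataset(self.df.copy(), dict(self.kinds), self.suppressed)

    def numeric(self, attribute: str) -> np.ndarray:
        """Parse a column as floats (suppressed rows yield NaN)."""
        vals = pd.to_numeric(self.df[attribute], errors="coerce").to_numpy(float)
        vals[self.suppressed] = np.nan
        return vals

    def rendered(self) -> pd.DataFrame:
        """Output view: suppressed rows fully starred."""
        out = self.df.copy()
        if self.suppressed.any():
            out.loc[self.suppressed, :] = SUPPRESSION_TOKEN
        return out

    def __eq__(self, other: object) -> bool:  # cell-wise, for tests
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.df.equals(other.df)
            and np.array_equal(self.suppressed, other.suppressed)
            and self.kinds == other.kinds
        )


@dataclass
class AttributeConfig:
    """Roles and transformation attachments for every attribute.

    ``roles`` maps attribute name to one of ``quasi_identifying_feature``,
    ``target`` or ``excluded``; ``hierarchies`` attaches a generalization
    hierarchy to any attribute that may be generalized (targets included —
    multi-target transformation is supported); ``aggregate`` lists numeric
    attributes replaced by their per-class statistic.
    """

    roles: dict[str, str]
    hierarchies: dict[str, Hierarchy] = field(default_factory=dict)
    aggregate: set[str] = field(default_factory=set)
    aggregate_statistic: str = "mean"

    def __post_init__(self) -> None:
        for a, r in self.roles.items():
            if r not in ROLES:
                raise ConfigError(f"attribute {a!r}: unknown role {r!r}")

    @property
    def quasi_identifiers(self) -> list[str]:
        return [a for a, r in self.roles.items() if r == "quasi_identifying_feature"]

    @property
    def targets(self) -> list[str]:
        return [a for a, r in self.roles.items() if r == "target"]

    def require_targets(self) -> None:
        if not self.targets:
            raise ConfigError("at least one target attribute is required")

    def validate_against(self, d: Dataset) -> None:
        for a in self.roles:
            if a not in d.attributes:
                raise ConfigError(f"configured attribute {a!r} not in dataset")


@dataclass(frozen=True)
class GeneralizationScheme:
    """One generalization level per quasi-identifying attribute — a node
    of the full-domain generalization lattice."""

    levels: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, levels: Mapping[str, int]) -> "GeneralizationScheme":
        return cls(tuple(levels.items()))

    def as_dict(self) -> dict[str, int]:
        return dict(self.levels)

    def level(self, attribute: str) -> int:
        return dict(self.levels).get(attribute, 0)

    @property
    def total(self) -> int:
        return sum(l for _, l in self.levels)

    def __str__(self) -> str:
        return "[" + ", ".join(f"{a}:{l}" for a, l in self.levels) + "]"


@dataclass
class Partition:
    """Equivalence classes over the transformed quasi-identifiers."""

    classes: list[np.ndarray]
    suppressed: np.ndarray

    def __post_init__(self) -> None:
        self.suppressed = np.asarray(self.suppressed, dtype=int)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.classes]

    @property
    def min_size(self) -> int:
        sizes = self.sizes
        return min(sizes) if sizes else 0

    @property
    def n_unsuppressed(self) -> int:
        return sum(self.sizes)

    @property
    def n_records(self) -> int:
        return self.n_unsuppressed + len(self.suppressed)


def load_dataset(
    path,
    kinds: Mapping[str, str] | None = None,
    config: AttributeConfig | None = None,
    delimiter: str = ",",
) -> Dataset:
    """Read a delimited text dataset with a header row.

    Numeric columns must parse as numbers in every row; empty cells become
    the category ``"NA"`` in categorical columns and are an error in
    numeric ones (unless the attribute is excluded by ``config``).
    """
    df = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, skipinitialspace=False
    )
    kinds = dict(kinds or {})
    if config is not None:
        config_attrs = set(config.roles)
        missing = config_attrs - set(df.columns)
        if missing:
            raise ConfigError(f"{path}: configured attributes missing: {sorted(missing)}")
    excluded = set()
    if config is not None:
        excluded = {a for a, r in config.roles.items() if r == "excluded"}
    df = df.replace("", "NA")
    for a in df.columns:
        kind = kinds.get(a, "categorical")
        if kind == "numeric" and a not in excluded:
            parsed = pd.to_numeric(df[a], errors="coerce")
            bad = parsed.isna()
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise DatasetFormatError(
                    f"{path}: non-numeric value {df[a].iloc[row]!r} in numeric "
                    f"attribute {a!r}, row {row + 2}"
                )
    return Dataset(df, kinds)


def write_dataset(d: Dataset, path, delimiter: str = ",") -> None:
    d.rendered().to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def apply_scheme(
    d: Dataset,
    scheme: GeneralizationScheme,
    hierarchies: Mapping[str, Hierarchy],
    unknown: str = "error",
) -> Dataset:
    """Full-domain generalization: replace every quasi-identifier cell by
    its representation at the scheme's level.  The input is not modified."""
    out = d.copy()
    for attr, level in scheme.levels:
        if level == 0:
            continue
        h = hierarchies.get(attr)
        if h is None:
            raise ConfigError(f"attribute {attr!r} has no hierarchy")
        col = out.df[attr].tolist()
        cache: dict[str, str] = {}
        new = []
        for v in col:
            g = cache.get(v)
            if g is None:
                g = h.generalize(v, level, unknown=unknown)
                cache[v] = g
            new.append(g)
        out.df[attr] = new
    return out


def compute_partition(d: Dataset, qi_attributes: Sequence[str]) -> Partition:
    """Group unsuppressed records by exact tuple equality over the
    (transformed) quasi-identifiers."""
    for a in qi_attributes:
        if a not in d.attributes:
            raise ConfigError(f"unknown attribute {a!r}")
    idx = np.flatnonzero(~d.suppressed)
    if len(idx) == 0:
        classes: list[np.ndarray] = []
    elif len(qi_attributes) == 0:
        classes = [idx]
    else:
        sub = d.df.iloc[idx][list(qi_attributes)]
        codes = np.zeros(len(idx), dtype=np.int64)
        for a in qi_attributes:
            c, uniques = pd.factorize(sub[a], sort=False)
            codes = codes * max(len(uniques), 1) + c
        _, inv = np.unique(codes, return_inverse=True)
        order = np.argsort(inv, kind="stable")
        boundaries = np.flatnonzero(np.diff(inv[order])) + 1
        classes = [np.sort(idx[order[s]]) for s in _slices(boundaries, len(order))]
    return Partition(classes=classes, suppressed=np.flatnonzero(d.suppressed))


def _slices(boundaries: np.ndarray, n: int):
    start = 0
    for b in list(boundaries) + [n]:
        yield slice(start, b)
        start = b


def suppress_small_classes(
    d: Dataset, p: Partition, k: int, limit: float = 1.0
) -> tuple[Dataset, Partition]:
    """Flag every record in an equivalence class of size < ``k``.

    Raises :class:`InfeasibleError` if doing so would push the overall
    suppressed fraction above ``limit``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= limit <= 1:
        raise ValueError("limit must be in [0, 1]")
    doomed = [c for c in p.classes if len(c) < k]
    kept = [c for c in p.classes if len(c) >= k]
    n_new = sum(len(c) for c in doomed)
    total_suppressed = len(p.suppressed) + n_new
    n = p.n_records
    if n > 0 and total_suppressed / n > limit + 1e-12:
        raise InfeasibleError(
            f"suppressing classes below size {k} would remove "
            f"{total_suppressed}/{n} records, exceeding limit {limit:.0%}"
        )
    out = d.copy()
    for c in doomed:
        out.suppressed[c] = True
    new_sup = np.flatnonzero(out.suppressed)
    return out, Partition(classes=kept, suppressed=new_sup)


def sample_records(d: Dataset, beta: float, seed: int) -> Dataset:
    """Bernoulli random sampling: keep each record independently with
    probability ``beta``.  Records not kept are removed outright (sampling
    happens before anonymization, so they never appear in the output)."""
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(d.n_records) < beta
    out = Dataset(d.df.loc[keep], dict(d.kinds), d.suppressed[keep])
    return out


def aggregate_attribute(
    d: Dataset, p: Partition, attribute: str, statistic: str = "mean", precision: int = 6
) -> Dataset:
    """Replace a numeric attribute's values by the per-class statistic."""
    if d.kinds.get(attribute) != "numeric":
        raise TypeError(f"attribute {attribute!r} is not numeric")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    vals = pd.to_numeric(d.df[attribute], errors="coerce").to_numpy(float)
    out = d.copy()
    col = out.df[attribute].to_numpy(object)
    for c in p.classes:
        v = vals[c]
        v = v[~np.isnan(v)]
        if len(v) == 0:
            continue
        stat = float(np.mean(v)) if statistic == "mean" else float(np.median(v))
        col[c] = f"{stat:.{precision}g}"
    out.df[attribute] = col
    return out


def suppress_cells(d: Dataset, cells: Iterable[tuple[int, str]]) -> Dataset:
    """Replace individual cells by the suppression token.  Passing every
    row of one attribute implements attribute suppression."""
    out = d.copy()
    for row, attr in cells:
        out.df.at[row, attr] = SUPPRESSION_TOKEN
    return out
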