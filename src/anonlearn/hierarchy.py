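"""Generalization hierarchies.

A hierarchy maps every original ("leaf") value of an attribute through
successively coarser representations up to a fully generalized root,
conventionally ``"*"``.  Level 0 is the original value; level L is the
root.  Hierarchies drive full-domain generalization: transforming an
attribute "to level ℓ" replaces every cell by its level-ℓ representation.

Files use the common export dialect of anonymization tools: delimited
text, no header, one row per leaf value, one column per level.
"""

from __future__ import annotations

import csv
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import (
    DomainError,
    HierarchyFormatError,
    HierarchyValidationError,
    UnknownValueError,
)

__all__ = [
    "Hierarchy",
    "IntervalSpec",
    "load_hierarchy",
    "write_hierarchy",
    "build_interval_hierarchy",
]


@dataclass(frozen=True)
class IntervalSpec:
    """Categorization rule for a numeric attribute.

    Parameters
    ----------
    cuts:
        Strictly increasing cut points.  Consecutive cut points define the
        half-open level-1 intervals ``[c_i, c_{i+1})``; their union is the
        declared domain ``[cuts[0], cuts[-1])``.
    merge_factor:
        How many adjacent intervals are merged per additional level (>= 2).
        Merging repeats until a single interval covers the domain.
    step:
        Sampling step used to enumerate the leaf values stored in the
        hierarchy table (leaves are only a convenience; arbitrary numeric
        values inside the domain are generalized analytically).
    label_fmt:
        Format string for interval labels, receiving ``lo`` and ``hi``.
    """

    cuts: tuple[float, ...]
    merge_factor: int = 2
    step: float = 1.0
    label_fmt: str = "[{lo:g},{hi:g})"

    def __post_init__(self) -> None:
        if len(self.cuts) < 2:
            raise HierarchyValidationError("interval spec needs >= 2 cut points")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise HierarchyValidationError("cut points must be strictly increasing")
        if self.merge_factor < 2:
            raise HierarchyValidationError("merge factor must be >= 2")
        if self.step <= 0:
            raise HierarchyValidationError("step must be positive")

    def label(self, lo: float, hi: float) -> str:
        return self.label_fmt.format(lo=lo, hi=hi)

    @property
    def domain(self) -> tuple[float, float]:
        return self.cuts[0], self.cuts[-1]

    def level_bounds(self) -> list[list[float]]:
        """Cut-point list for every level >= 1 (level 1 first)."""
        bounds = [list(self.cuts)]
        while len(bounds[-1]) > 2:
            prev = bounds[-1]
            inner = prev[1:-1]
            merged = [prev[0]] + inner[self.merge_factor - 1 :: self.merge_factor]
            if merged[-1] != prev[-1]:
                merged.append(prev[-1])
            bounds.append(merged)
        return bounds


class Hierarchy:
    """A validated generalization hierarchy for one attribute.

    ``table`` maps each leaf value to its representations at levels
    ``0..L`` (a tuple whose first entry is the leaf itself).
    """

    def __init__(
        self,
        attribute: str,
        rows: Iterable[Sequence[str]],
        interval_spec: IntervalSpec | None = None,
    ) -> None:
        self.attribute = attribute
        self.interval_spec = interval_spec
        rows = [tuple(str(c) for c in r) for r in rows]
        if not rows:
            raise HierarchyFormatError(f"hierarchy for {attribute!r} has no rows")
        width = len(rows[0])
        if width < 1:
            raise HierarchyFormatError(f"hierarchy for {attribute!r} has no columns")
        for i, r in enumerate(rows):
            if len(r) != width:
                raise HierarchyFormatError(
                    f"hierarchy for {attribute!r}: row {i + 1} has {len(r)} "
                    f"columns, expected {width}"
                )
        table: dict[str, tuple[str, ...]] = {}
        for r in rows:
            if r[0] in table:
                raise HierarchyValidationError(
                    f"hierarchy for {attribute!r}: duplicate leaf value {r[0]!r}"
                )
            table[r[0]] = r
        self.table = table
        self._rows = rows
        self._check_coarsening()
        # index: generalized label -> (level, witness leaf); lowest level wins
        self._label_index: dict[str, tuple[int, str]] = {}
        for r in rows:
            for lev in range(width - 1, 0, -1):
                self._label_index[r[lev]] = (lev, r[0])
        self._level_bounds = interval_spec.level_bounds() if interval_spec else None

    def _check_coarsening(self) -> None:
        # coarsening holds iff every level->next-level mapping is functional
        for lev in range(self.levels - 1):
            seen: dict[str, tuple[str, str]] = {}
            for r in self._rows:
                key, nxt = r[lev], r[lev + 1]
                if key in seen and seen[key][0] != nxt:
                    raise HierarchyValidationError(
                        f"hierarchy for {self.attribute!r}: leaves "
                        f"{seen[key][1]!r} and {r[0]!r} share {key!r} at level "
                        f"{lev} but diverge at level {lev + 1}"
                    )
                seen.setdefault(key, (nxt, r[0]))

    @property
    def levels(self) -> int:
        """Number of levels including level 0."""
        return len(self._rows[0])

    @property
    def max_level(self) -> int:
        return self.levels - 1

    @property
    def leaves(self) -> list[str]:
        return [r[0] for r in self._rows]

    def root_values(self) -> set[str]:
        return {r[-1] for r in self._rows}

    def generalize(self, value: str, level: int, unknown: str = "error") -> str:
        """Return the level-``level`` representation of ``value``.

        ``value`` may be a leaf or an already-generalized label of level
        <= ``level`` (making repeated application idempotent).  Unknown
        values follow ``unknown``: ``"error"`` raises, ``"top"`` maps to
        the root (which must be single-valued).
        """
        if not 0 <= level <= self.max_level:
            raise ValueError(
                f"level {level} outside 0..{self.max_level} for {self.attribute!r}"
            )
        value = str(value)
        if level == 0:
            return value
        row = self.table.get(value)
        if row is not None:
            return row[level]
        hit = self._label_index.get(value)
        if hit is not None:
            lev, leaf = hit
            if lev <= level:
                return self.table[leaf][level]
        if self.interval_spec is not None:
            try:
                x = float(value)
            except ValueError:
                pass
            else:
                return self._generalize_numeric(x, level)
        if unknown == "top":
            roots = self.root_values()
            if len(roots) == 1:
                return next(iter(roots))
            raise UnknownValueError(
                f"hierarchy for {self.attribute!r}: cannot map unknown value "
                f"{value!r} to a multi-valued top level"
            )
        raise UnknownValueError(
            f"hierarchy for {self.attribute!r}: unknown value {value!r}"
        )

    def _generalize_numeric(self, x: float, level: int) -> str:
        assert self.interval_spec is not None and self._level_bounds is not None
        lo, hi = self.interval_spec.domain
        if not (lo <= x < hi):
            raise DomainError(
                f"value {x!r} outside declared domain [{lo},{hi}) of "
                f"attribute {self.attribute!r}"
            )
        bounds = self._level_bounds[min(level, len(self._level_bounds)) - 1]
        i = bisect_right(bounds, x) - 1
        i = min(i, len(bounds) - 2)
        return self.interval_spec.label(bounds[i], bounds[i + 1])


def generalize_value(h: Hierarchy, value: str, level: int, unknown: str = "error") -> str:
    """Functional alias for :meth:`Hierarchy.generalize`."""
    return h.generalize(value, level, unknown=unknown)


def load_hierarchy(path, attribute: str | None = None, delimiter: str = ";") -> Hierarchy:
    """Read a hierarchy from delimited text (no header, column j = level j)."""
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if rows and len(row) != len(rows[0]):
                raise HierarchyFormatError(
                    f"{path}: line {lineno} has {len(row)} fields, expected "
                    f"{len(rows[0])}"
                )
            rows.append(row)
    name = attribute if attribute is not None else str(path)
    return Hierarchy(name, rows)


def write_hierarchy(h: Hierarchy, path, delimiter: str = ";") -> None:
    """Write ``h`` in the same dialect :func:`load_hierarchy` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        for leaf in h.leaves:
            writer.writerow(h.table[leaf])


def build_interval_hierarchy(attribute: str, spec: IntervalSpec) -> Hierarchy:
    """Build a hierarchy that categorizes a numeric domain.

    Level 1 holds the interval labels defined by the cut points; each
    further level merges ``merge_factor`` adjacent intervals until a single
    interval covers the whole domain.  Leaves sample the domain at
    ``spec.step``; values between samples are generalized analytically by
    interval membership.
    """
    levels_bounds = spec.level_bounds()
    lo, hi = spec.domain
    leaves: list[float] = []
    x = lo
    n_steps = int(math.ceil((hi - lo) / spec.step))
    for i in range(n_steps):
        x = lo + i * spec.step
        if x < hi:
            leaves.append(x)
    rows = []
    for leaf in leaves:
        row = [f"{leaf:g}"]
        for bounds in levels_bounds:
            i = bisect_right(bounds, leaf) - 1
            i = min(i, len(bounds) - 2)
            row.append(spec.label(bounds[i], bounds[i + 1]))
        rows.append(row)
    return Hierarchy(attribute, rows, interval_spec=spec)
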