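"""The decision matrix: alternatives, criteria, mixed cells, and weight handling.

A decision problem is an ``n x K`` grid of evaluations ``f_k(a)`` of ``n``
alternatives on ``K`` criteria.  Cells may be crisp numbers (a cost, an error
rate) or linguistic terms from a fuzzy scale (a throughput category);
``resolve_cells`` defuzzifies the latter so the outranking engine always sees
a numeric grid.  Each criterion declares an optimization direction, a weight
(numeric or linguistic), and a preference-function spec; ``resolve_weights``
defuzzifies linguistic weights and normalizes the vector to sum 1, which
bounds the aggregated preference index in [0, 1] and makes flows comparable
across problems with different numbers of criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np

from .fuzzy import (
    DEFAULT_SCALE,
    FuzzyScale,
    LinguisticTerm,
    MissingScaleEntryError,
    term_to_value,
    yager_index,
)

__all__ = [
    "InvalidWeightError",
    "MatrixStructureError",
    "Direction",
    "PreferenceFunctionSpec",
    "Criterion",
    "Alternative",
    "CellValue",
    "DecisionMatrix",
    "ValidationIssue",
    "ValidationReport",
    "resolve_cells",
    "resolve_weights",
    "validate_matrix",
]

MAXIMIZE = "maximize"
MINIMIZE = "minimize"
Direction = str  # one of MAXIMIZE / MINIMIZE

PREFERENCE_KINDS = ("usual", "u_shape", "v_shape", "level", "linear", "gaussian")


class InvalidWeightError(ValueError):
    """Raised for a non-positive numeric criterion weight."""


class MatrixStructureError(ValueError):
    """Raised when a decision matrix violates a hard structural invariant."""


@dataclass(frozen=True)
class PreferenceFunctionSpec:
    """Which of the six classical preference functions a criterion uses.

    ``q`` is the indifference threshold, ``p`` the strict-preference
    threshold, ``s`` the Gaussian spread.  ``s="auto"`` asks the engine to
    estimate the spread as the sample standard deviation of the criterion's
    resolved column, which makes the Gaussian preference scale-free.
    """

    kind: str = "gaussian"
    q: float = 0.0
    p: Optional[float] = None
    s: Union[float, str, None] = "auto"

    def __post_init__(self) -> None:
        if self.kind not in PREFERENCE_KINDS:
            raise ValueError(f"unknown preference function kind {self.kind!r}")
        if self.q < 0:
            raise ValueError("indifference threshold q must be >= 0")
        if self.kind == "gaussian":
            if self.s is None or (isinstance(self.s, str) and self.s != "auto"):
                raise ValueError("gaussian preference needs s > 0 or s='auto'")
            # s == 0 arises when the spread is estimated from a constant
            # column; the engine then assigns zero preference on that criterion
            if isinstance(self.s, (int, float)) and self.s < 0:
                raise ValueError("gaussian spread s must be >= 0")
        if self.kind in ("v_shape", "linear", "level") and (self.p is None or self.p <= 0):
            raise ValueError(f"{self.kind} preference needs a threshold p > 0")
        if self.kind == "level" and self.p is not None and self.p < self.q:
            raise ValueError("level preference needs p >= q")
        if self.kind == "linear" and self.p is not None and self.p <= self.q:
            raise ValueError("linear preference needs p > q")


@dataclass(frozen=True)
class Criterion:
    id: str
    label: str = ""
    direction: Direction = MAXIMIZE
    weight: Union[LinguisticTerm, float] = 1.0
    preference: PreferenceFunctionSpec = field(default_factory=PreferenceFunctionSpec)

    def __post_init__(self) -> None:
        if self.direction not in (MAXIMIZE, MINIMIZE):
            raise ValueError(f"direction must be maximize/minimize, got {self.direction!r}")
        if not isinstance(self.weight, LinguisticTerm):
            if not isinstance(self.weight, (int, float)):
                raise InvalidWeightError(f"weight must be a term or a number, got {self.weight!r}")
            if self.weight <= 0:
                raise InvalidWeightError(f"numeric weight must be > 0, got {self.weight}")


@dataclass(frozen=True)
class Alternative:
    id: str
    label: str = ""
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CellValue:
    """Exactly one of a crisp number or a linguistic term.

    The optional ``unit`` annotation is informational only; cells within one
    criterion column are assumed already comparable.
    """

    numeric: Optional[float] = None
    linguistic: Optional[LinguisticTerm] = None
    # informational only, excluded from equality (CSV cells carry no units)
    unit: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if (self.numeric is None) == (self.linguistic is None):
            raise ValueError("a cell holds either a numeric value or a linguistic term")
        if self.numeric is not None and not np.isfinite(self.numeric):
            raise ValueError(f"numeric cell must be finite, got {self.numeric}")

    @property
    def is_linguistic(self) -> bool:
        return self.linguistic is not None

    def resolve(self, scale: FuzzyScale) -> float:
        if self.numeric is not None:
            return float(self.numeric)
        return term_to_value(self.linguistic, scale)

    @classmethod
    def of(cls, value: Union[float, str, LinguisticTerm], unit: str = "") -> "CellValue":
        """Coerce a raw value: numbers stay numeric, strings/terms go linguistic."""
        if isinstance(value, LinguisticTerm):
            return cls(linguistic=value, unit=unit)
        if isinstance(value, str):
            return cls(linguistic=LinguisticTerm.parse(value), unit=unit)
        return cls(numeric=float(value), unit=unit)


@dataclass(frozen=True)
class DecisionMatrix:
    """Complete evaluation grid plus criterion metadata and the fuzzy scale.

    Construction enforces the hard invariants: a complete ``n x K`` grid of
    :class:`CellValue` with unique alternative and criterion ids.  Soft
    requirements (``n >= 2`` for flows to be defined, non-constant columns)
    are reported by :func:`validate_matrix` and enforced by the engine.
    """

    alternatives: Sequence[Alternative]
    criteria: Sequence[Criterion]
    cells: Sequence[Sequence[CellValue]]  # row-major, n x K
    scale: FuzzyScale = DEFAULT_SCALE

    def __post_init__(self) -> None:
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "cells", tuple(tuple(row) for row in self.cells))
        n, k = len(self.alternatives), len(self.criteria)
        if n < 1 or k < 1:
            raise MatrixStructureError("need at least one alternative and one criterion")
        if len(self.cells) != n:
            raise MatrixStructureError(f"expected {n} cell rows, got {len(self.cells)}")
        for i, row in enumerate(self.cells):
            if len(row) != k:
                raise MatrixStructureError(f"row {i} has {len(row)} cells, expected {k}")
            for j, cell in enumerate(row):
                if not isinstance(cell, CellValue):
                    raise MatrixStructureError(f"cell ({i},{j}) is missing or not a CellValue")
        ids = [a.id for a in self.alternatives]
        if len(set(ids)) != len(ids):
            raise MatrixStructureError("duplicate alternative ids")
        cids = [c.id for c in self.criteria]
        if len(set(cids)) != len(cids):
            raise MatrixStructureError("duplicate criterion ids")

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    def alternative_ids(self) -> List[str]:
        return [a.id for a in self.alternatives]

    def criterion_ids(self) -> List[str]:
        return [c.id for c in self.criteria]

    def criterion_index(self, criterion_id: str) -> int:
        for i, c in enumerate(self.criteria):
            if c.id == criterion_id:
                return i
        raise KeyError(f"unknown criterion id {criterion_id!r}")

    def with_criteria(self, criteria: Sequence[Criterion]) -> "DecisionMatrix":
        return replace(self, criteria=tuple(criteria))


def resolve_cells(matrix: DecisionMatrix) -> np.ndarray:
    """Defuzzify the grid: numeric cells pass through, linguistic cells are
    mapped through the matrix's fuzzy scale via the Yager index.

    Returns an ``(n, K)`` float array with no missing entries.  A linguistic
    cell whose term is absent from the scale raises
    :class:`~fpromethee.fuzzy.MissingScaleEntryError`.
    """
    n, k = matrix.n_alternatives, matrix.n_criteria
    out = np.empty((n, k), dtype=float)
    for i, row in enumerate(matrix.cells):
        for j, cell in enumerate(row):
            out[i, j] = cell.resolve(matrix.scale)
    return out


def resolve_weights(
    criteria: Sequence[Criterion], scale: FuzzyScale = DEFAULT_SCALE
) -> np.ndarray:
    """Defuzzify linguistic weights and normalize the vector to sum 1.

    Numeric weights are used as-is (must be > 0); linguistic weights become
    their Yager-index value under ``scale``.  Normalization preserves ratios,
    so scaling every numeric weight by the same positive constant leaves the
    result unchanged.
    """
    raw = np.empty(len(criteria), dtype=float)
    for i, c in enumerate(criteria):
        if isinstance(c.weight, LinguisticTerm):
            raw[i] = yager_index(scale[c.weight])
        else:
            if c.weight <= 0:
                raise InvalidWeightError(f"criterion {c.id}: weight must be > 0")
            raw[i] = float(c.weight)
    if np.any(raw <= 0):
        bad = [criteria[i].id for i in np.nonzero(raw <= 0)[0]]
        raise InvalidWeightError(f"non-positive resolved weight for criteria {bad}")
    return raw / raw.sum()


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" or "warning"
    message: str


@dataclass(frozen=True)
class ValidationReport:
    issues: Sequence[ValidationIssue]

    @property
    def violations(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_matrix(matrix: DecisionMatrix) -> ValidationReport:
    """Report all soft violations and warnings for a structurally valid matrix.

    Errors: fewer than two alternatives (outranking flows divide by n - 1),
    linguistic terms absent from the scale, non-positive weights.  Warnings:
    constant (zero-spread) criterion columns, which contribute nothing to the
    ranking.
    """
    issues: List[ValidationIssue] = []
    if matrix.n_alternatives < 2:
        issues.append(ValidationIssue("error", "n < 2: ranking needs at least two alternatives"))
    for j, c in enumerate(matrix.criteria):
        if isinstance(c.weight, LinguisticTerm) and c.weight not in matrix.scale:
            issues.append(ValidationIssue(
                "error", f"criterion {c.id}: weight term {c.weight.value} missing from scale"))
    for i, row in enumerate(matrix.cells):
        for j, cell in enumerate(row):
            if cell.is_linguistic and cell.linguistic not in matrix.scale:
                issues.append(ValidationIssue(
                    "error",
                    f"cell ({matrix.alternatives[i].id}, {matrix.criteria[j].id}): "
                    f"term {cell.linguistic.value} missing from scale"))
    if not issues:  # spreads only meaningful once all cells resolve
        grid = resolve_cells(matrix)
        for j, c in enumerate(matrix.criteria):
            col = grid[:, j]
            if np.ptp(col) == 0:
                issues.append(ValidationIssue(
                    "warning", f"criterion {c.id}: zero-spread (constant) column"))
    return ValidationReport(tuple(issues))
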