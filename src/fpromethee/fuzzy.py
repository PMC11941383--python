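"""Triangular fuzzy numbers, linguistic scales, and Yager-index defuzzification.

Multi-criteria evaluations are often elicited verbally ("accuracy is Very
High") rather than numerically.  This module provides the fuzzy layer that
turns such judgments into crisp numbers: a five-level linguistic scale whose
terms map to triangular fuzzy numbers, and the Yager index, which collapses a
triangular fuzzy number ``(N, a, b)`` — peak ``N``, left spread ``a``, right
spread ``b`` — to the single value ``(3N - a + b) / 3``.  Algebraically this
equals the triangle centroid ``(lower + mode + upper) / 3``, a fact the test
suite exploits as an independent oracle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "InvalidFuzzyNumberError",
    "MissingScaleEntryError",
    "TriangularFuzzyNumber",
    "LinguisticTerm",
    "FuzzyScale",
    "DEFAULT_SCALE",
    "make_tfn",
    "yager_index",
    "term_to_value",
]


class InvalidFuzzyNumberError(ValueError):
    """Raised when (lower, mode, upper) violates lower <= mode <= upper."""


class MissingScaleEntryError(KeyError):
    """Raised when a linguistic term has no entry in the active fuzzy scale."""


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """A triangular fuzzy number stored as its three abscissae.

    ``lower`` and ``upper`` carry membership 0, ``mode`` carries membership 1.
    The spread form used in the defuzzification formula is derived:
    ``left_spread = mode - lower`` and ``right_spread = upper - mode``.
    The degenerate case ``lower == mode == upper`` is a crisp number.
    """

    lower: float
    mode: float
    upper: float

    def __post_init__(self) -> None:
        for name in ("lower", "mode", "upper"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or v != v or v in (float("inf"), float("-inf")):
                raise InvalidFuzzyNumberError(f"{name} must be a finite real, got {v!r}")
        if not (self.lower <= self.mode <= self.upper):
            raise InvalidFuzzyNumberError(
                f"requires lower <= mode <= upper, got ({self.lower}, {self.mode}, {self.upper})"
            )

    @property
    def left_spread(self) -> float:
        """Distance from the peak to the left bound (the 'a' of (N, a, b))."""
        return self.mode - self.lower

    @property
    def right_spread(self) -> float:
        """Distance from the peak to the right bound (the 'b' of (N, a, b))."""
        return self.upper - self.mode

    def defuzzify(self) -> float:
        return yager_index(self)


def make_tfn(lower: float, mode: float, upper: float) -> TriangularFuzzyNumber:
    """Build a validated triangular fuzzy number from its three abscissae."""
    return TriangularFuzzyNumber(float(lower), float(mode), float(upper))


def yager_index(x: TriangularFuzzyNumber) -> float:
    """Defuzzify via the Yager index (3N - a + b) / 3.

    With N the mode and a, b the left/right spreads this is the centroid of
    the triangle, so the result always lies in [lower, upper] and a symmetric
    fuzzy number defuzzifies to its mode.
    """
    return (3.0 * x.mode - x.left_spread + x.right_spread) / 3.0


class LinguisticTerm(enum.Enum):
    """Closed five-level verbal scale used for qualitative cells and weights."""

    VERY_LOW = "VL"
    LOW = "L"
    MODERATE = "M"
    HIGH = "H"
    VERY_HIGH = "VH"

    @classmethod
    def parse(cls, token: str) -> "LinguisticTerm":
        """Parse an abbreviation or full word, case-insensitively.

        Accepts 'VH', 'very high', 'VeryHigh', 'very_high', with surrounding
        whitespace ignored.
        """
        key = token.strip().upper().replace(" ", "").replace("_", "").replace("-", "")
        aliases = {
            "VL": cls.VERY_LOW, "VERYLOW": cls.VERY_LOW,
            "L": cls.LOW, "LOW": cls.LOW,
            "M": cls.MODERATE, "MODERATE": cls.MODERATE, "MEDIUM": cls.MODERATE,
            "H": cls.HIGH, "HIGH": cls.HIGH,
            "VH": cls.VERY_HIGH, "VERYHIGH": cls.VERY_HIGH,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unrecognized linguistic term {token!r}") from None


@dataclass(frozen=True)
class FuzzyScale:
    """An immutable mapping from linguistic terms to triangular fuzzy numbers.

    The scale is data, not code: the packaged default covers the five standard
    terms, but any subset (or an entirely different term set wrapped in
    :class:`LinguisticTerm`) may be supplied, e.g. from a config file.
    """

    mapping: Mapping[LinguisticTerm, TriangularFuzzyNumber]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))
        if not self.mapping:
            raise ValueError("a fuzzy scale needs at least one term")

    def __getitem__(self, term: LinguisticTerm) -> TriangularFuzzyNumber:
        try:
            return self.mapping[term]
        except KeyError:
            raise MissingScaleEntryError(
                f"term {term} has no entry in this fuzzy scale"
            ) from None

    def __contains__(self, term: LinguisticTerm) -> bool:
        return term in self.mapping

    def terms(self) -> Iterable[LinguisticTerm]:
        return self.mapping.keys()

    def value_of(self, term: LinguisticTerm) -> float:
        return term_to_value(term, self)


#: Default five-level scale: VH=(0.75,1,1), H=(0.50,0.75,1), M=(0.25,0.50,0.75),
#: L=(0,0.25,0.50), VL=(0,0,0.25).
DEFAULT_SCALE = FuzzyScale({
    LinguisticTerm.VERY_HIGH: make_tfn(0.75, 1.0, 1.0),
    LinguisticTerm.HIGH: make_tfn(0.50, 0.75, 1.0),
    LinguisticTerm.MODERATE: make_tfn(0.25, 0.50, 0.75),
    LinguisticTerm.LOW: make_tfn(0.0, 0.25, 0.50),
    LinguisticTerm.VERY_LOW: make_tfn(0.0, 0.0, 0.25),
})


def term_to_value(term: LinguisticTerm, scale: FuzzyScale = DEFAULT_SCALE) -> float:
    """Defuzzified numeric value of a linguistic term under the given scale."""
    return yager_index(scale[term])
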