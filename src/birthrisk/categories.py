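"""Birth risk-category taxonomy and per-birth classification.

Births are classified along three dimensions empirically associated with
under-five mortality risk:

* **spacing** — preceding birth interval in months, four categories
  (``<18mo``, ``18-23mo``, ``24-35mo``, ``36+mo``); undefined for first
  births;
* **mothers_age** — mother's completed age at birth in years, three
  categories (``<18``, ``18-34``, ``35+``);
* **parity** — birth order, three categories (``first``, ``2-4``, ``5+``).

All category bounds are half-open intervals ``[lo, hi)``, which makes each
dimension's categories disjoint and exhaustive: an interval of exactly 24
months falls in ``24-35mo``, a mother aged exactly 35 in ``35+``.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass

from .errors import ValidationError

SPACING = "spacing"
MOTHERS_AGE = "mothers_age"
PARITY = "parity"
DIMENSIONS = (SPACING, MOTHERS_AGE, PARITY)


@dataclass(frozen=True)
class CategoryBin:
    """One category: values in ``[lo, hi)`` carry ``label``."""

    label: str
    lo: float
    hi: float

    def __contains__(self, value: float) -> bool:
        return self.lo <= value < self.hi


@dataclass(frozen=True)
class CategorySpec:
    """Ordered, disjoint, exhaustive categories along one risk dimension."""

    dimension: str
    bins: tuple[CategoryBin, ...]

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ValidationError(f"unknown dimension {self.dimension!r}",
                                  field="dimension")
        for a, b in zip(self.bins, self.bins[1:]):
            if not (a.lo < a.hi and a.hi == b.lo):
                raise ValidationError(
                    f"bins of {self.dimension!r} must be increasing and "
                    f"contiguous; got [{a.lo},{a.hi}) then [{b.lo},{b.hi})",
                    field="categories")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.bins)

    def locate(self, value: float) -> str:
        """Return the label of the bin containing ``value``."""
        for b in self.bins:
            if value in b:
                return b.label
        raise ValidationError(
            f"value {value} outside the domain of {self.dimension!r} "
            f"([{self.bins[0].lo}, {self.bins[-1].hi}))", field=self.dimension)


def default_specs() -> dict[str, CategorySpec]:
    """The standard taxonomy: 4 spacing, 3 age, 3 parity categories."""
    inf = math.inf
    return {
        SPACING: CategorySpec(SPACING, (
            CategoryBin("<18mo", 0, 18),
            CategoryBin("18-23mo", 18, 24),
            CategoryBin("24-35mo", 24, 36),
            CategoryBin("36+mo", 36, inf),
        )),
        MOTHERS_AGE: CategorySpec(MOTHERS_AGE, (
            CategoryBin("<18", 0, 18),
            CategoryBin("18-34", 18, 35),
            CategoryBin("35+", 35, inf),
        )),
        PARITY: CategorySpec(PARITY, (
            CategoryBin("first", 1, 2),
            CategoryBin("2-4", 2, 5),
            CategoryBin("5+", 5, inf),
        )),
    }


def all_category_keys(specs: Mapping[str, CategorySpec] | None = None,
                      ) -> list[tuple[str, str]]:
    """All (dimension, label) pairs in canonical order."""
    specs = specs or default_specs()
    return [(dim, lab) for dim in DIMENSIONS for lab in specs[dim].labels]


def validate_birth(birth: Mapping, *, row: int | None = None) -> None:
    """Check a single birth record's internal invariants.

    Raises :class:`ValidationError` naming the offending field.
    """
    order = birth.get("birth_order")
    if order is None or order < 1 or order != int(order):
        raise ValidationError("birth_order must be a positive integer",
                              field="birth_order", row=row)
    preceding = birth.get("preceding_interval_months")
    missing = preceding is None or (isinstance(preceding, float)
                                    and math.isnan(preceding))
    if order == 1 and not missing:
        raise ValidationError(
            "preceding interval must be absent for first births",
            field="preceding_interval_months", row=row)
    if order > 1:
        if missing:
            raise ValidationError(
                "preceding interval required for births of order >= 2",
                field="preceding_interval_months", row=row)
        if preceding <= 0:
            raise ValidationError("preceding interval must be positive",
                                  field="preceding_interval_months", row=row)
    age = birth.get("mother_age_at_birth_years")
    if age is None or age < 0:
        raise ValidationError("mother's age at birth must be nonnegative",
                              field="mother_age_at_birth_years", row=row)


def classify_birth(birth: Mapping,
                   specs: Mapping[str, CategorySpec] | None = None,
                   ) -> dict[str, str]:
    """Classify one birth into a label per dimension.

    ``birth`` is any mapping with ``birth_order``,
    ``mother_age_at_birth_years`` and (for order >= 2)
    ``preceding_interval_months``. The spacing key is absent from the
    result for first births, which have no preceding interval.
    """
    specs = specs or default_specs()
    validate_birth(birth)
    out = {
        PARITY: specs[PARITY].locate(birth["birth_order"]),
        MOTHERS_AGE: specs[MOTHERS_AGE].locate(
            birth["mother_age_at_birth_years"]),
    }
    if birth["birth_order"] > 1:
        out[SPACING] = specs[SPACING].locate(
            birth["preceding_interval_months"])
    return out
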