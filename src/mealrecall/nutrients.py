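"""Core nutrient data model.

Nutrient amounts are carried as :class:`NutrientVector` objects — a mapping
from canonical nutrient keys (``energy_kcal``, ``protein_g``, ...) to
non-negative amounts, tagged with the basis the amounts are expressed on
(per 100 g of food, per day, or per portion).  All downstream arithmetic
(meal profiles, daily totals, %TEI shares) goes through this type so that
vectors on incompatible bases can never be mixed silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Basis",
    "MealType",
    "NutrientVector",
    "EnergyFactors",
    "MealRecord",
    "CANONICAL_NUTRIENTS",
    "meal_profile",
    "percent_tei",
    "salt_from_sodium",
]


class Basis(str, Enum):
    """Basis a nutrient vector is expressed on."""

    PER_100G = "per_100g"
    PER_DAY = "per_day"
    PER_PORTION = "per_portion"


class MealType(str, Enum):
    """The five eating-occasion categories used throughout the pipeline."""

    BREAKFAST = "breakfast"
    LIGHT_MEAL = "light_meal"
    MAIN_MEAL = "main_meal"
    SNACK = "snack"
    BEVERAGE = "beverage"


#: The 16 nutrient variables the comparison tables are built from.  Unknown
#: keys are carried through all arithmetic untouched.
CANONICAL_NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "carbohydrate_g",
    "sugar_g",
    "fiber_g",
    "fat_g",
    "saturated_fat_g",
    "monounsaturated_fat_g",
    "polyunsaturated_fat_g",
    "vitamin_d_ug",
    "folate_ug",
    "vitamin_c_mg",
    "calcium_mg",
    "iron_mg",
    "potassium_mg",
    "sodium_mg",
)


class BasisMismatchError(ValueError):
    """Arithmetic attempted between vectors on different bases."""


@dataclass(frozen=True)
class NutrientVector:
    """Immutable map nutrient key -> non-negative amount, on a fixed basis.

    Parameters
    ----------
    values:
        Mapping from nutrient key to amount.  Amounts must be >= 0.
    basis:
        The basis all amounts share.  Set once at construction.
    """

    values: Mapping[str, float]
    basis: Basis

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for key, amount in self.values.items():
            amount = float(amount)
            if amount < 0:
                raise ValueError(f"negative amount for {key!r}: {amount}")
            clean[key] = amount
        object.__setattr__(self, "values", clean)
        object.__setattr__(self, "basis", Basis(self.basis))

    def __getitem__(self, key: str) -> float:
        """Amount for *key*; absent nutrients read as 0."""
        return self.values.get(key, 0.0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def keys(self):
        return self.values.keys()

    def add(self, other: "NutrientVector") -> "NutrientVector":
        """Component-wise sum.  Bases must match."""
        if self.basis is not other.basis:
            raise BasisMismatchError(
                f"cannot add {self.basis.value} to {other.basis.value}"
            )
        keys = set(self.values) | set(other.values)
        return NutrientVector(
            {k: self[k] + other[k] for k in keys}, self.basis
        )

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return self.add(other)

    def scale(self, factor: float, basis: Basis | None = None) -> "NutrientVector":
        """Multiply every amount by *factor* (>= 0); optionally re-tag basis.

        Re-tagging is how a per-100 g profile becomes a per-day contribution
        once multiplied by an actual consumed weight.
        """
        if factor < 0:
            raise ValueError(f"scale factor must be >= 0, got {factor}")
        return NutrientVector(
            {k: v * factor for k, v in self.values.items()},
            basis if basis is not None else self.basis,
        )

    @classmethod
    def zero(cls, basis: Basis) -> "NutrientVector":
        return cls({}, basis)

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


@dataclass(frozen=True)
class EnergyFactors:
    """Metabolisable-energy conversion factors, kcal per gram of macro.

    Defaults follow the UK/CoFID convention (protein 4, carbohydrate 3.75,
    fat 9, alcohol 7) since the comparator instrument's food list is
    CoFID-based; all four are configurable.
    """

    protein: float = 4.0
    carbohydrate: float = 3.75
    fat: float = 9.0
    alcohol: float = 7.0

    def __post_init__(self) -> None:
        for name in ("protein", "carbohydrate", "fat", "alcohol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"energy factor {name} must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "protein": self.protein,
            "carbohydrate": self.carbohydrate,
            "fat": self.fat,
            "alcohol": self.alcohol,
        }


@dataclass
class MealRecord:
    """One eating occasion from a weighed diary.

    ``total_weight_g`` is always the sum of the food weights and
    ``profile_per100g`` the weight-weighted mean of the food per-100 g
    profiles; use :meth:`from_foods` to construct records that satisfy both
    invariants.
    """

    participant_id: str
    day_index: int
    occasion_label: str
    meal_type: MealType | None
    foods: list[tuple[str, float]]
    total_weight_g: float
    profile_per100g: NutrientVector
    meal_id: str = ""
    hour: float | None = None
    weekend: bool = False

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError("day_index must be >= 1")
        if not self.foods:
            raise ValueError("a meal must contain at least one food")
        if self.total_weight_g <= 0:
            raise ValueError("total_weight_g must be > 0")
        if not self.meal_id:
            self.meal_id = (
                f"{self.participant_id}:d{self.day_index}:{self.occasion_label}"
            )

    @classmethod
    def from_foods(
        cls,
        participant_id: str,
        day_index: int,
        occasion_label: str,
        items: Iterable[tuple[str, float, NutrientVector]],
        meal_type: MealType | None = None,
        **kwargs,
    ) -> "MealRecord":
        """Build a record from ``(food_id, weight_g, per-100 g profile)`` items."""
        items = list(items)
        foods = [(fid, w) for fid, w, _ in items]
        profile = meal_profile([(p, w) for _, w, p in items])
        return cls(
            participant_id=participant_id,
            day_index=day_index,
            occasion_label=occasion_label,
            meal_type=meal_type,
            foods=foods,
            total_weight_g=sum(w for _, w in foods),
            profile_per100g=profile,
            **kwargs,
        )

    def intake(self) -> NutrientVector:
        """Absolute nutrient intake of this occasion (per-day contribution)."""
        return self.profile_per100g.scale(self.total_weight_g / 100.0, Basis.PER_DAY)


def meal_profile(
    foods: Iterable[tuple[NutrientVector, float]],
) -> NutrientVector:
    """Weight-weighted mean of food per-100 g profiles.

    Parameters
    ----------
    foods:
        ``(per-100 g profile, weight_g)`` pairs, weights > 0.

    Returns
    -------
    NutrientVector on the per-100 g basis.
    """
    foods = list(foods)
    if not foods:
        raise ValueError("meal_profile requires at least one food")
    total = 0.0
    acc: dict[str, float] = {}
    for profile, weight in foods:
        if weight <= 0:
            raise ValueError(f"food weight must be > 0, got {weight}")
        if profile.basis is not Basis.PER_100G:
            raise BasisMismatchError("food profiles must be per_100g")
        total += weight
        for key in profile.keys():
            acc[key] = acc.get(key, 0.0) + profile[key] * weight
    return NutrientVector({k: v / total for k, v in acc.items()}, Basis.PER_100G)


#: macro key in a per-day vector -> (gram key, energy-factor attribute)
MACRO_TEI_MAP: dict[str, tuple[str, str]] = {
    "protein": ("protein_g", "protein"),
    "carbohydrate": ("carbohydrate_g", "carbohydrate"),
    "sugar": ("sugar_g", "carbohydrate"),
    "total_fat": ("fat_g", "fat"),
    "saturated_fat": ("saturated_fat_g", "fat"),
    "monounsaturated_fat": ("monounsaturated_fat_g", "fat"),
    "polyunsaturated_fat": ("polyunsaturated_fat_g", "fat"),
    "alcohol": ("alcohol_g", "alcohol"),
}


def percent_tei(
    day: NutrientVector, factors: EnergyFactors = EnergyFactors()
) -> dict[str, float]:
    """Percent of total energy intake contributed by each macronutrient.

    For each macro ``m``: ``100 * grams(m) * kcal_per_g(m) / energy_kcal``.
    Sugar uses the carbohydrate factor; all fat fractions use the fat factor.

    Raises
    ------
    ValueError
        If the day's energy is missing or not positive.
    """
    energy = day["energy_kcal"]
    if energy <= 0:
        raise ValueError("percent_tei requires energy_kcal > 0")
    out: dict[str, float] = {}
    for macro, (gram_key, factor_name) in MACRO_TEI_MAP.items():
        grams = day[gram_key]
        out[macro] = 100.0 * grams * getattr(factors, factor_name) / energy
    return out


def salt_from_sodium(sodium_mg: float) -> float:
    """Convert sodium (mg) to salt equivalent (g): ``mg * 2.5 / 1000``."""
    if sodium_mg < 0:
        raise ValueError("sodium must be >= 0")
    return sodium_mg * 2.5 / 1000.0
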