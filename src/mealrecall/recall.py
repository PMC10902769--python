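"""Scoring engine: recall responses -> daily nutrient intakes.

Respondents answer per meal slot (breakfast, three snack slots, lunch,
evening meal, beverages).  A food-meal answer picks a generic meal, one of
three displayed portion images (septiles 2/4/6) and a smaller/same/larger
follow-up, which together resolve to one of the seven septile portions.
Beverages pick a displayed portion directly plus a count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .derive import GenericMeal, MealBank
from .nutrients import Basis, MealType, NutrientVector

__all__ = [
    "Slot",
    "Relative",
    "RecallResponse",
    "DayIntake",
    "SLOT_MEAL_TYPE",
    "PORTION_EMISSION",
    "resolve_portion",
    "meal_intake",
    "beverage_intake",
    "score_day",
]


class Slot(str, Enum):
    BREAKFAST = "breakfast"
    MORNING_SNACK = "morning_snack"
    LUNCH = "lunch"
    AFTERNOON_SNACK = "afternoon_snack"
    EVENING_MEAL = "evening_meal"
    EVENING_SNACK = "evening_snack"
    BEVERAGE = "beverage"


class Relative(str, Enum):
    """Follow-up answer: how the displayed image compared with what was eaten."""

    SMALLER = "image_smaller_than_consumed"
    SAME = "same"
    LARGER = "image_larger_than_consumed"


#: Fixed slot -> bank meal-type mapping.  The single snack bank serves all
#: three snack slots.
SLOT_MEAL_TYPE: dict[Slot, MealType] = {
    Slot.BREAKFAST: MealType.BREAKFAST,
    Slot.MORNING_SNACK: MealType.SNACK,
    Slot.LUNCH: MealType.LIGHT_MEAL,
    Slot.AFTERNOON_SNACK: MealType.SNACK,
    Slot.EVENING_MEAL: MealType.MAIN_MEAL,
    Slot.EVENING_SNACK: MealType.SNACK,
    Slot.BEVERAGE: MealType.BEVERAGE,
}

_DISPLAYED_IMAGES = (2, 4, 6)

#: Canonical (image_index, relative) pair emitting each septile portion;
#: portions 3 and 5 are reachable from two images — this is the fixed
#: convention simulators use.
PORTION_EMISSION: dict[int, tuple[int, Relative]] = {
    1: (2, Relative.LARGER),
    2: (2, Relative.SAME),
    3: (2, Relative.SMALLER),
    4: (4, Relative.SAME),
    5: (6, Relative.LARGER),
    6: (6, Relative.SAME),
    7: (6, Relative.SMALLER),
}


@dataclass
class RecallResponse:
    """One answered meal slot.

    Either ``generic_meal_id`` is set (with image/relative, and count for
    beverage slots) or ``free_text`` records a none-of-the-above fallback.
    """

    participant_id: str
    slot: Slot
    generic_meal_id: str | None = None
    free_text: str | None = None
    image_index: int | None = None
    relative: Relative | None = None
    count: int | None = None

    def __post_init__(self) -> None:
        self.slot = Slot(self.slot)
        if self.relative is not None:
            self.relative = Relative(self.relative)
        chosen = self.generic_meal_id is not None
        if chosen == (self.free_text is not None):
            raise ValueError(
                "exactly one of generic_meal_id and free_text must be given"
            )
        if chosen:
            if self.slot is Slot.BEVERAGE:
                if self.image_index not in _DISPLAYED_IMAGES:
                    raise ValueError("beverage responses need an image index in {2,4,6}")
                if self.count is None or self.count < 1:
                    raise ValueError("beverage responses need count >= 1")
            else:
                if self.image_index is None or self.relative is None:
                    raise ValueError("food-meal responses need image_index and relative")
        else:
            if self.image_index is not None or self.relative is not None:
                raise ValueError("none-of-the-above responses carry no portion answers")


@dataclass
class DayIntake:
    """Daily totals plus the resolved/unresolved meal bookkeeping."""

    participant_id: str
    totals: NutrientVector
    resolved_meals: list[tuple[Slot, str, int, float]] = field(default_factory=list)
    unresolved: list[tuple[Slot, str]] = field(default_factory=list)


def resolve_portion(image_index: int, relative: Relative) -> int:
    """Map a displayed image (septile 2, 4 or 6) and follow-up to a portion index.

    ``smaller than consumed`` steps up one septile, ``larger`` steps down,
    ``same`` keeps the displayed one — reaching every index 1..7.
    """
    if image_index not in _DISPLAYED_IMAGES:
        raise ValueError(f"image index must be one of {_DISPLAYED_IMAGES}, got {image_index}")
    delta = {Relative.SMALLER: 1, Relative.SAME: 0, Relative.LARGER: -1}[Relative(relative)]
    return image_index + delta


def meal_intake(gm: GenericMeal, portion_index: int) -> NutrientVector:
    """Nutrient intake of one generic meal at a septile portion.

    ``profile_per100g * portion_weight / 100``, returned on the per-day
    basis so meal contributions sum directly into daily totals.
    """
    if not 1 <= portion_index <= 7:
        raise ValueError(f"portion index must be in 1..7, got {portion_index}")
    weight = gm.portion_weights_g[portion_index - 1]
    return gm.profile_per100g.scale(weight / 100.0, Basis.PER_DAY)


def beverage_intake(gm: GenericMeal, image_index: int, count: int) -> NutrientVector:
    """Beverage intake: the displayed portion taken ``count`` times.

    Beverages have no smaller/same/larger follow-up; the displayed septile
    is consumed directly.
    """
    if count < 1:
        raise ValueError(f"beverage count must be >= 1, got {count}")
    if image_index not in _DISPLAYED_IMAGES:
        raise ValueError(f"image index must be one of {_DISPLAYED_IMAGES}, got {image_index}")
    return meal_intake(gm, image_index).scale(float(count))


def score_day(responses: list[RecallResponse], bank: MealBank) -> DayIntake:
    """Resolve one day of recall responses against a generic-meal bank.

    None-of-the-above answers are recorded in ``unresolved`` and contribute
    zero nutrients; skipped slots simply do not appear.  Totals are the sum
    of all resolved meal intakes (order-invariant).

    Raises
    ------
    KeyError
        Unknown generic meal id.
    ValueError
        A chosen meal's type does not match its slot.
    """
    pid = responses[0].participant_id if responses else ""
    totals = NutrientVector.zero(Basis.PER_DAY)
    day = DayIntake(participant_id=pid, totals=totals)
    for resp in responses:
        if resp.free_text is not None:
            day.unresolved.append((resp.slot, resp.free_text))
            continue
        gm = bank.get(resp.generic_meal_id)
        expected = SLOT_MEAL_TYPE[resp.slot]
        if gm.meal_type is not expected:
            raise ValueError(
                f"generic meal {gm.id!r} has type {gm.meal_type.value}, "
                f"but slot {resp.slot.value} requires {expected.value}"
            )
        if resp.slot is Slot.BEVERAGE:
            intake = beverage_intake(gm, resp.image_index, resp.count)
            portion = resp.image_index
            weight = gm.portion_weights_g[portion - 1] * resp.count
        else:
            portion = resolve_portion(resp.image_index, resp.relative)
            intake = meal_intake(gm, portion)
            weight = gm.portion_weights_g[portion - 1]
        day.totals = day.totals + intake
        day.resolved_meals.append((resp.slot, gm.id, portion, weight))
    return day
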