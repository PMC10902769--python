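import numpy as np
import pytest

from mealrecall.derive import GenericMeal, MealBank
from mealrecall.nutrients import Basis, MealType, NutrientVector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def vec100(**kwargs) -> NutrientVector:
    return NutrientVector(kwargs, Basis.PER_100G)


def make_generic(gm_id, meal_type, energy=100.0, portions=None, **nutrients):
    portions = portions or [100, 150, 200, 250, 300, 350, 400]
    return GenericMeal(
        id=gm_id,
        meal_type=meal_type,
        profile_per100g=vec100(energy_kcal=energy, **nutrients),
        portion_weights_g=list(portions),
        member_meal_ids=[f"{gm_id}_m0"],
        medoid_meal_id=f"{gm_id}_m0",
    )


@pytest.fixture
def tiny_bank():
    meals = [
        make_generic("breakfast_1", MealType.BREAKFAST, energy=150.0, protein_g=5.0),
        make_generic("light_meal_1", MealType.LIGHT_MEAL, energy=120.0, protein_g=8.0),
        make_generic("main_meal_1", MealType.MAIN_MEAL, energy=180.0, protein_g=12.0),
        make_generic("snack_1", MealType.SNACK, energy=400.0, sugar_g=30.0,
                     portions=[30, 40, 50, 60, 70, 80, 90]),
        make_generic("beverage_1", MealType.BEVERAGE, energy=40.0, sugar_g=9.0,
                     portions=[125, 150, 200, 250, 330, 400, 500]),
    ]
    return MealBank(meals, provenance={"source": "fixture"})
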