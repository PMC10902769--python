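"""Synthetic cohorts with known ground truth.

Emulates the structure the pipeline expects from a national weighed-diary
survey (multi-food meals with weights, several days per person, five meal
types) and a paired-method comparison cohort: a noisy food-level comparator
instrument and a structurally-erroneous generic recall (meal mismatch plus
portion quantisation, optionally a systematic bias multiplier).

All randomness flows from one ``numpy.random.default_rng(seed)``; cohorts
regenerate bit-identically from their config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .derive import MealBank, derive_bank
from .nrf import ReferenceIntakes
from .nutrients import Basis, EnergyFactors, MealRecord, MealType, NutrientVector
from .recall import (
    PORTION_EMISSION,
    RecallResponse,
    Slot,
    meal_intake,
    score_day,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_foods",
    "generate_diary",
    "observe_24hr",
    "observe_generic",
    "sample_days_from_bank",
    "generate_cohort",
    "estimate_multiplicative_bias",
]

BEVERAGE_GROUP = "beverages"

_MEAL_BASE_WEIGHT = {
    MealType.BREAKFAST: 350.0,
    MealType.LIGHT_MEAL: 400.0,
    MealType.MAIN_MEAL: 550.0,
    MealType.SNACK: 150.0,
    MealType.BEVERAGE: 250.0,
}

_TYPE_SLOT = {
    MealType.BREAKFAST: Slot.BREAKFAST,
    MealType.LIGHT_MEAL: Slot.LUNCH,
    MealType.MAIN_MEAL: Slot.EVENING_MEAL,
    MealType.SNACK: Slot.MORNING_SNACK,
    MealType.BEVERAGE: Slot.BEVERAGE,
}

#: per-100 g scale of each generated nutrient (median of the group bases)
_NUTRIENT_SCALES = {
    "protein_g": 8.0,
    "carbohydrate_g": 15.0,
    "fat_g": 8.0,
    "fiber_g": 2.0,
    "vitamin_d_ug": 1.0,
    "folate_ug": 30.0,
    "vitamin_c_mg": 10.0,
    "calcium_mg": 80.0,
    "iron_mg": 1.5,
    "potassium_mg": 250.0,
    "sodium_mg": 300.0,
    "vitamin_a_ug": 100.0,
    "vitamin_e_mg": 2.0,
    "magnesium_mg": 40.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic world.  ``seed`` is mandatory."""

    seed: int
    n_foods: int = 60
    n_food_groups: int = 6
    n_participants: int = 40
    days_per_person: int = 4
    meal_template_count: dict = field(
        default_factory=lambda: {
            "breakfast": 3,
            "light_meal": 3,
            "main_meal": 4,
            "snack": 3,
            "beverage": 2,
        }
    )
    portion_lognormal_sigma: float = 0.25
    noise_24hr_sigma: float = 0.0
    recall_mismatch_prob: float = 0.0
    bias_factor: float = 1.0
    snack_prob: float = 0.7
    beverage_prob: float = 0.8
    food_noise_sigma: float = 0.3
    k_per_type: dict = field(default_factory=lambda: {"default": 2})
    energy_factors: EnergyFactors = field(default_factory=EnergyFactors)
    from_bank: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.recall_mismatch_prob, self.snack_prob, self.beverage_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for s in (self.portion_lognormal_sigma, self.noise_24hr_sigma, self.food_noise_sigma):
            if s < 0:
                raise ValueError("sigmas must be >= 0")
        if self.n_foods < self.n_food_groups:
            raise ValueError("need at least one food per group")


def _group_names(config: SimulationConfig) -> list[str]:
    names = [f"group_{i}" for i in range(config.n_food_groups - 1)]
    return names + [BEVERAGE_GROUP]


def generate_foods(
    config: SimulationConfig,
    rng: np.random.Generator,
    return_bases: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Food composition table with energy consistent with the macro grams.

    Per-group lognormal base profiles; each food jitters its group base by
    an independent lognormal factor per nutrient.  Sugar is a fixed
    per-group fraction of carbohydrate, and the fat subtypes split the fat
    total, so compositional invariants hold by construction.  Energy is
    recomputed as ``sum(grams * kcal_per_g)``.
    """
    groups = _group_names(config)
    f = config.energy_factors
    bases: dict[str, dict[str, float]] = {}
    fractions: dict[str, dict[str, float]] = {}
    for g in groups:
        watery = 0.15 if g == BEVERAGE_GROUP else 1.0
        bases[g] = {
            key: scale * watery * rng.lognormal(0.0, 0.5)
            for key, scale in _NUTRIENT_SCALES.items()
        }
        sat, mono, poly, _ = rng.dirichlet([2, 2, 1, 2])
        fractions[g] = {
            "sugar": float(rng.beta(2, 3)),
            "sat": float(sat),
            "mono": float(mono),
            "poly": float(poly),
        }
    rows = []
    for i in range(config.n_foods):
        g = groups[i % len(groups)]
        base = bases[g]
        frac = fractions[g]
        row = {"food_id": f"food_{i:04d}", "food_group": g}
        for key in _NUTRIENT_SCALES:
            row[key] = base[key] * rng.lognormal(0.0, config.food_noise_sigma)
        row["sugar_g"] = row["carbohydrate_g"] * frac["sugar"]
        row["saturated_fat_g"] = row["fat_g"] * frac["sat"]
        row["monounsaturated_fat_g"] = row["fat_g"] * frac["mono"]
        row["polyunsaturated_fat_g"] = row["fat_g"] * frac["poly"]
        row["energy_kcal"] = (
            row["protein_g"] * f.protein
            + row["carbohydrate_g"] * f.carbohydrate
            + row["fat_g"] * f.fat
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    if return_bases:
        return df, {"bases": bases, "fractions": fractions}
    return df


def _food_profiles(foods: pd.DataFrame) -> dict[str, NutrientVector]:
    nutrient_cols = [c for c in foods.columns if c not in ("food_id", "food_group")]
    return {
        rec["food_id"]: NutrientVector(
            {c: float(rec[c]) for c in nutrient_cols}, Basis.PER_100G
        )
        for rec in foods.to_dict("records")
    }


def _make_templates(
    foods: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> dict[MealType, list[dict]]:
    """Meal templates: a food-group mixture and a base weight per template."""
    groups = _group_names(config)
    food_groups = [g for g in groups if g != BEVERAGE_GROUP]
    templates: dict[MealType, list[dict]] = {}
    for mtype in MealType:
        count = int(config.meal_template_count.get(mtype.value, 2))
        templates[mtype] = []
        for _ in range(count):
            if mtype is MealType.BEVERAGE:
                chosen = [BEVERAGE_GROUP]
                mix = np.ones(1)
            else:
                n_groups = int(rng.integers(1, min(3, len(food_groups)) + 1))
                chosen = list(
                    rng.choice(food_groups, size=n_groups, replace=False)
                )
                mix = rng.dirichlet(np.ones(n_groups) * 3)
            templates[mtype].append(
                {
                    "groups": chosen,
                    "mix": mix,
                    "base_weight": _MEAL_BASE_WEIGHT[mtype]
                    * float(rng.lognormal(0.0, 0.15)),
                }
            )
    return templates


def generate_diary(
    foods: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[MealRecord], pd.DataFrame]:
    """Weighed-diary meal records plus exact true daily intakes.

    Every person-day has a breakfast, a light meal and a main meal; snacks
    and beverages appear with their configured probabilities.  Meals realise
    a randomly drawn template with a lognormal total weight.
    """
    profiles = _food_profiles(foods)
    by_group: dict[str, list[str]] = {}
    for rec in foods.itertuples():
        by_group.setdefault(rec.food_group, []).append(rec.food_id)
    templates = _make_templates(foods, config, rng)

    meals: list[MealRecord] = []
    truth_rows = []
    for p in range(config.n_participants):
        pid = f"p{p:04d}"
        for day in range(1, config.days_per_person + 1):
            day_types = [MealType.BREAKFAST, MealType.LIGHT_MEAL, MealType.MAIN_MEAL]
            if rng.random() < config.snack_prob:
                day_types.append(MealType.SNACK)
            if rng.random() < config.beverage_prob:
                day_types.append(MealType.BEVERAGE)
            totals = NutrientVector.zero(Basis.PER_DAY)
            for mtype in day_types:
                tpl = templates[mtype][int(rng.integers(len(templates[mtype])))]
                total_w = tpl["base_weight"] * float(
                    rng.lognormal(0.0, config.portion_lognormal_sigma)
                )
                items = []
                for g, frac in zip(tpl["groups"], tpl["mix"]):
                    fid = by_group[g][int(rng.integers(len(by_group[g])))]
                    items.append((fid, max(total_w * float(frac), 1e-6), profiles[fid]))
                meal = MealRecord.from_foods(
                    pid, day, mtype.value, items, meal_type=mtype
                )
                meals.append(meal)
                totals = totals + meal.intake()
            truth_rows.append(
                {"participant_id": pid, "day": day, **totals.as_dict()}
            )
    truth = pd.DataFrame(truth_rows).fillna(0.0)
    return meals, truth


def observe_24hr(
    day_meals: Sequence[MealRecord], sigma: float, rng: np.random.Generator
) -> NutrientVector:
    """Comparator-instrument observation: each meal's intake multiplied by an
    i.i.d. multiplicative lognormal error, then summed over the day."""
    totals = NutrientVector.zero(Basis.PER_DAY)
    for meal in day_meals:
        factor = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
        totals = totals + meal.intake().scale(factor)
    return totals


def _bank_feature_stats(bank: MealBank) -> tuple[list[str], dict]:
    keys = sorted(
        {k for gm in bank.generic_meals for k in gm.profile_per100g.keys()}
    )
    mat = np.array(
        [[gm.profile_per100g[k] for k in keys] for gm in bank.generic_meals]
    )
    sd = mat.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return keys, {"mean": mat.mean(axis=0), "sd": sd}


def _nearest_portion(weights: Sequence[float], target: float) -> int:
    """1-based index of the septile weight nearest *target* (ties -> lower)."""
    best, best_gap = 1, abs(weights[0] - target)
    for i, w in enumerate(weights[1:], start=2):
        gap = abs(w - target)
        if gap < best_gap - 1e-12:
            best, best_gap = i, gap
    return best


def observe_generic(
    day_meals: Sequence[MealRecord],
    bank: MealBank,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[RecallResponse]:
    """Simulated respondent behaviour for one day.

    With probability ``1 - recall_mismatch_prob`` the respondent picks the
    same-type generic meal nearest their true meal in standardised nutrient
    space, otherwise a uniformly random same-type one.  The portion answer
    is the septile whose weight is nearest the true meal weight, emitted
    through the fixed image/relative convention; beverages report the
    nearest displayed image (septile 2/4/6) with count 1.
    """
    keys, stats = _bank_feature_stats(bank)
    responses = []
    for meal in day_meals:
        candidates = bank.by_type(meal.meal_type)
        if not candidates:
            raise ValueError(f"bank has no generic meals of type {meal.meal_type.value}")
        if rng.random() < config.recall_mismatch_prob:
            gm = candidates[int(rng.integers(len(candidates)))]
        else:
            vec = np.array([meal.profile_per100g[k] for k in keys])
            dists = []
            for cand in candidates:
                cvec = np.array([cand.profile_per100g[k] for k in keys])
                dists.append(
                    float(np.linalg.norm((vec - cvec) / stats["sd"]))
                )
            gm = candidates[int(np.argmin(dists))]
        slot = _TYPE_SLOT[meal.meal_type]
        if meal.meal_type is MealType.BEVERAGE:
            gaps = [
                abs(gm.portion_weights_g[i - 1] - meal.total_weight_g)
                for i in (2, 4, 6)
            ]
            image = (2, 4, 6)[int(np.argmin(gaps))]
            responses.append(
                RecallResponse(
                    participant_id=meal.participant_id,
                    slot=slot,
                    generic_meal_id=gm.id,
                    image_index=image,
                    count=1,
                )
            )
        else:
            portion = _nearest_portion(gm.portion_weights_g, meal.total_weight_g)
            image, relative = PORTION_EMISSION[portion]
            responses.append(
                RecallResponse(
                    participant_id=meal.participant_id,
                    slot=slot,
                    generic_meal_id=gm.id,
                    image_index=image,
                    relative=relative,
                )
            )
    return responses


def sample_days_from_bank(
    bank: MealBank, config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[tuple[str, int], list[RecallResponse]]]:
    """Round-trip cohort: true meals ARE bank meals at septile weights.

    Each person-day draws generic meals (breakfast, light meal, main meal,
    plus probabilistic snack/beverage) at uniformly random septile portions;
    the true intake is exactly what :func:`mealrecall.recall.score_day`
    should reproduce from the emitted responses.
    """
    truth_rows = []
    responses: dict[tuple[str, int], list[RecallResponse]] = {}
    for p in range(config.n_participants):
        pid = f"p{p:04d}"
        for day in range(1, config.days_per_person + 1):
            day_types = [MealType.BREAKFAST, MealType.LIGHT_MEAL, MealType.MAIN_MEAL]
            if rng.random() < config.snack_prob:
                day_types.append(MealType.SNACK)
            if rng.random() < config.beverage_prob:
                day_types.append(MealType.BEVERAGE)
            totals = NutrientVector.zero(Basis.PER_DAY)
            resp: list[RecallResponse] = []
            for mtype in day_types:
                pool = bank.by_type(mtype)
                if not pool:
                    continue
                gm = pool[int(rng.integers(len(pool)))]
                slot = _TYPE_SLOT[mtype]
                if mtype is MealType.BEVERAGE:
                    image = int(rng.choice([2, 4, 6]))
                    count = int(rng.integers(1, 3))
                    totals = totals + meal_intake(gm, image).scale(float(count))
                    resp.append(
                        RecallResponse(
                            participant_id=pid,
                            slot=slot,
                            generic_meal_id=gm.id,
                            image_index=image,
                            count=count,
                        )
                    )
                else:
                    portion = int(rng.integers(1, 8))
                    totals = totals + meal_intake(gm, portion)
                    image, relative = PORTION_EMISSION[portion]
                    resp.append(
                        RecallResponse(
                            participant_id=pid,
                            slot=slot,
                            generic_meal_id=gm.id,
                            image_index=image,
                            relative=relative,
                        )
                    )
            truth_rows.append({"participant_id": pid, "day": day, **totals.as_dict()})
            responses[(pid, day)] = resp
    return pd.DataFrame(truth_rows).fillna(0.0), responses


@dataclass
class SyntheticCohort:
    """Everything a full pipeline run needs, with ground truth attached."""

    config: SimulationConfig
    foods: pd.DataFrame
    diary_meals: list[MealRecord]
    truth: pd.DataFrame  # per participant-day
    bank: MealBank
    responses: dict[tuple[str, int], list[RecallResponse]]
    intakes_24hr: pd.DataFrame  # per participant (day-averaged)
    intakes_generic: pd.DataFrame  # per participant (day-averaged, bias applied)

    def food_groups(self) -> dict[str, str]:
        return dict(zip(self.foods["food_id"], self.foods["food_group"]))


def _average_days(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows).fillna(0.0)
    return df.drop(columns="day").groupby("participant_id").mean().sort_index()


def generate_cohort(
    config: SimulationConfig, refs: ReferenceIntakes | None = None
) -> SyntheticCohort:
    """Run the full synthetic pipeline under one seed.

    Generates foods and a diary, derives a generic-meal bank from that diary,
    then observes each person-day through both instruments.  When
    ``config.from_bank`` is set the true meals are re-drawn from the bank
    (round-trip mode: the generic method has zero structural error).
    ``bias_factor`` multiplies the generic-side intakes.
    """
    if refs is None:
        refs = ReferenceIntakes.default()
    rng = np.random.default_rng(config.seed)
    foods = generate_foods(config, rng)
    meals, truth = generate_diary(foods, config, rng)
    food_groups = dict(zip(foods["food_id"], foods["food_group"]))
    bank = derive_bank(
        meals,
        refs,
        food_groups,
        {"k": config.k_per_type, "source": "synthetic"},
        seed=config.seed,
    )

    if config.from_bank:
        truth, responses = sample_days_from_bank(bank, config, rng)
        by_day: dict[tuple[str, int], NutrientVector] = {
            (rec["participant_id"], int(rec["day"])): NutrientVector(
                {
                    k: v
                    for k, v in rec.items()
                    if k not in ("participant_id", "day")
                },
                Basis.PER_DAY,
            )
            for rec in truth.to_dict("records")
        }
        obs24_rows = []
        for (pid, day), vec in by_day.items():
            factor = (
                float(rng.lognormal(0.0, config.noise_24hr_sigma))
                if config.noise_24hr_sigma > 0
                else 1.0
            )
            obs24_rows.append(
                {"participant_id": pid, "day": day, **vec.scale(factor).as_dict()}
            )
    else:
        day_meals: dict[tuple[str, int], list[MealRecord]] = {}
        for meal in meals:
            day_meals.setdefault((meal.participant_id, meal.day_index), []).append(meal)
        responses = {}
        obs24_rows = []
        for (pid, day), mlist in day_meals.items():
            obs = observe_24hr(mlist, config.noise_24hr_sigma, rng)
            obs24_rows.append({"participant_id": pid, "day": day, **obs.as_dict()})
            responses[(pid, day)] = observe_generic(mlist, bank, config, rng)

    generic_rows = []
    for (pid, day), resp in responses.items():
        intake = score_day(resp, bank)
        generic_rows.append(
            {
                "participant_id": pid,
                "day": day,
                **intake.totals.scale(config.bias_factor).as_dict(),
            }
        )
    intakes_24hr = _average_days(obs24_rows)
    intakes_generic = _average_days(generic_rows)
    return SyntheticCohort(
        config=config,
        foods=foods,
        diary_meals=meals,
        truth=truth,
        bank=bank,
        responses=responses,
        intakes_24hr=intakes_24hr,
        intakes_generic=intakes_generic,
    )


def estimate_multiplicative_bias(
    intakes_a: pd.DataFrame, intakes_b: pd.DataFrame, nutrient: str = "energy_kcal"
) -> float:
    """``exp(mean log(B/A))`` over participants: the geometric-mean ratio of
    method B to method A for one nutrient."""
    a = intakes_a[nutrient].to_numpy(dtype=float)
    b = intakes_b.loc[intakes_a.index, nutrient].to_numpy(dtype=float)
    ok = (a > 0) & (b > 0)
    return float(np.exp(np.mean(np.log(b[ok] / a[ok]))))
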