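"""Derivation of a generic-meal bank from meal-level diary data.

Pipeline: type each diary occasion, build per-meal features (profiling score
plus food-group weight fractions, z-scored), cluster each meal type with
k-medoids (PAM, BUILD+SWAP), then summarise each cluster as a generic meal:
the unweighted mean per-100 g nutrient profile of its members and seven
septile portion weights.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import silhouette_score

from .nrf import ReferenceIntakes, nrf93
from .nutrients import Basis, MealRecord, MealType, NutrientVector

logger = logging.getLogger(__name__)

__all__ = [
    "MealTypeRules",
    "MealTypeError",
    "GenericMeal",
    "MealBank",
    "PamResult",
    "assign_meal_type",
    "build_features",
    "pam",
    "select_k",
    "septile_portions",
    "derive_bank",
]


class MealTypeError(ValueError):
    """An occasion label could not be mapped to a meal type."""


@dataclass(frozen=True)
class MealTypeRules:
    """Deterministic occasion -> meal-type mapping.

    Precedence: explicit label map, then beverage-only composition test,
    then time-of-day bands (``(start_hour, end_hour, type)``, start
    inclusive, end exclusive).
    """

    label_map: Mapping[str, MealType] = field(default_factory=dict)
    beverage_groups: frozenset[str] = frozenset({"beverages"})
    time_bands: tuple[tuple[float, float, MealType], ...] = ()


def assign_meal_type(
    meal: MealRecord,
    rules: MealTypeRules,
    food_groups: Mapping[str, str] | None = None,
) -> MealType:
    """Resolve the meal type of a diary occasion.

    Raises
    ------
    MealTypeError
        If no rule covers the occasion; the message names the label.
    """
    label = meal.occasion_label.strip().lower()
    if label in rules.label_map:
        return MealType(rules.label_map[label])
    if food_groups is not None and meal.foods:
        groups = {food_groups.get(fid) for fid, _ in meal.foods}
        if groups and groups <= set(rules.beverage_groups):
            return MealType.BEVERAGE
    if meal.hour is not None:
        for lo, hi, mtype in rules.time_bands:
            if lo <= meal.hour < hi:
                return MealType(mtype)
    raise MealTypeError(f"cannot assign a meal type to occasion {meal.occasion_label!r}")


def build_features(
    meals: Sequence[MealRecord],
    refs: ReferenceIntakes,
    food_groups: Mapping[str, str],
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix for clustering: [NRF score, food-group weight fractions].

    One row per meal.  Group fractions are each food group's share of the
    meal's total weight (they sum to 1 before standardisation).  Every column
    is z-scored; constant columns are dropped and logged.

    Returns
    -------
    (matrix, feature_names) with matrix shape ``(n_meals, n_kept_features)``.
    """
    if len(meals) < 2:
        raise ValueError("build_features requires at least 2 meals")
    group_names = sorted(set(food_groups.values()))
    group_idx = {g: i for i, g in enumerate(group_names)}
    raw = np.zeros((len(meals), 1 + len(group_names)))
    for r, meal in enumerate(meals):
        raw[r, 0] = nrf93(meal.profile_per100g, refs)
        for fid, weight in meal.foods:
            g = food_groups.get(fid)
            if g is None:
                raise KeyError(f"food {fid!r} missing from the food-group table")
            raw[r, 1 + group_idx[g]] += weight / meal.total_weight_g
    names = ["nrf_score"] + [f"frac_{g}" for g in group_names]
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        logger.info("dropping constant feature columns: %s", dropped)
    if not keep.any():
        # all meals identical in feature space: keep a single zero column
        return np.zeros((len(meals), 1)), ["constant"]
    std = (raw[:, keep] - mean[keep]) / sd[keep]
    return std, [n for n, k in zip(names, keep) if k]


@dataclass(frozen=True)
class PamResult:
    medoids: tuple[int, ...]
    labels: np.ndarray
    cost: float


def _assignment_cost(dist: np.ndarray, medoids: Sequence[int]) -> tuple[np.ndarray, float]:
    sub = dist[:, list(medoids)]
    nearest = sub.argmin(axis=1)
    labels = np.asarray([medoids[i] for i in nearest])
    return labels, float(sub.min(axis=1).sum())


def _swap_descent(
    dist: np.ndarray, medoids: list[int], cost: float
) -> tuple[list[int], float]:
    """Steepest-descent SWAP phase: apply the best improving
    (medoid, non-medoid) exchange until none lowers the cost."""
    n = dist.shape[0]
    improved = True
    while improved:
        improved = False
        best: tuple[float, int | None, int | None] = (0.0, None, None)
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            for h in range(n):
                if h in med_set:
                    continue
                _, new_cost = _assignment_cost(dist, others + [h])
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            _, cost = _assignment_cost(dist, medoids)
            improved = True
    return medoids, cost


def pam(
    matrix: np.ndarray, k: int, seed: int | None = None, restarts: int = 8
) -> PamResult:
    """Partitioning around medoids on Euclidean distances (BUILD + SWAP).

    BUILD greedily seeds the k medoids (first: the point with minimal total
    distance to all others; then the point giving the largest cost drop),
    followed by a steepest-descent SWAP phase.  Because SWAP descends to a
    local optimum, *restarts* additional descents from seeded random medoid
    subsets are run and the lowest-cost solution kept.  Deterministic given
    *seed* (seed None behaves as seed 0).

    Returns medoid row indices (sorted), a label per row (the index of its
    assigned medoid) and the total distance cost.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))

    # BUILD
    medoids = [int(dist.sum(axis=1).argmin())]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        # cost after adding each candidate
        gains = np.minimum(current[None, :], dist).sum(axis=1)
        gains[medoids] = np.inf
        medoids.append(int(gains.argmin()))
    _, cost = _assignment_cost(dist, medoids)
    best_medoids, best_cost = _swap_descent(dist, medoids, cost)

    rng = np.random.default_rng(0 if seed is None else seed)
    for _ in range(restarts if k < n else 0):
        start = sorted(int(i) for i in rng.choice(n, size=k, replace=False))
        _, c0 = _assignment_cost(dist, start)
        cand, c = _swap_descent(dist, list(start), c0)
        if c < best_cost - 1e-12:
            best_medoids, best_cost = cand, c
    medoids = sorted(best_medoids)
    labels, cost = _assignment_cost(dist, medoids)
    return PamResult(tuple(medoids), labels, cost)


def select_k(
    matrix: np.ndarray, k_range: Iterable[int], seed: int | None = None
) -> int:
    """Pick the cluster count maximising average silhouette width.

    Ties go to the smallest k.  A singleton range is returned as-is.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("select_k requires a non-empty k range")
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if len(ks) == 1:
        return ks[0]
    best_k, best_sil = None, -np.inf
    for k in ks:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside the silhouette-valid range [2, {n - 1}]")
        res = pam(X, k, seed)
        sil = silhouette_score(X, res.labels)
        if sil > best_sil + 1e-12:
            best_k, best_sil = k, sil
    return best_k


def septile_portions(weights: Sequence[float]) -> list[float]:
    """Seven portion weights: medians of seven near-equal weight-ordered groups.

    Weights are sorted ascending and split into 7 contiguous groups with
    sizes as equal as possible; when ``n % 7 != 0`` the extra items go to the
    earliest groups.  Each portion is the median of its group.  With fewer
    than 7 meals, empty trailing groups inherit the nearest lower non-empty
    group's median (logged).
    """
    ws = sorted(float(w) for w in weights)
    if not ws:
        raise ValueError("septile_portions requires at least one weight")
    if ws[0] <= 0:
        raise ValueError("meal weights must be > 0")
    n = len(ws)
    base, rem = divmod(n, 7)
    portions: list[float] = []
    start = 0
    for s in range(7):
        size = base + (1 if s < rem else 0)
        group = ws[start : start + size]
        start += size
        if group:
            portions.append(float(median(group)))
        else:
            logger.info("septile group %d empty (n=%d); inheriting lower median", s + 1, n)
            portions.append(portions[-1])
    return portions


@dataclass
class GenericMeal:
    """A cluster of real meals summarised as one presentable meal."""

    id: str
    meal_type: MealType
    profile_per100g: NutrientVector
    portion_weights_g: list[float]
    member_meal_ids: list[str]
    medoid_meal_id: str

    def __post_init__(self) -> None:
        if len(self.portion_weights_g) != 7:
            raise ValueError("a generic meal carries exactly 7 portion weights")
        if any(b < a for a, b in zip(self.portion_weights_g, self.portion_weights_g[1:])):
            raise ValueError("portion weights must be non-decreasing")
        if any(w <= 0 for w in self.portion_weights_g):
            raise ValueError("portion weights must be > 0")
        if self.medoid_meal_id not in self.member_meal_ids:
            raise ValueError("medoid must be a member of its own cluster")

    @property
    def member_count(self) -> int:
        return len(self.member_meal_ids)


@dataclass
class MealBank:
    """The derived generic-meal bank plus provenance metadata."""

    generic_meals: list[GenericMeal]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [gm.id for gm in self.generic_meals]
        if len(ids) != len(set(ids)):
            raise ValueError("generic meal ids must be unique")

    def get(self, gm_id: str) -> GenericMeal:
        for gm in self.generic_meals:
            if gm.id == gm_id:
                return gm
        raise KeyError(f"unknown generic meal id {gm_id!r}")

    def by_type(self, meal_type: MealType) -> list[GenericMeal]:
        return [gm for gm in self.generic_meals if gm.meal_type is meal_type]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for gm in self.generic_meals:
            out[gm.meal_type.value] = out.get(gm.meal_type.value, 0) + 1
        return out


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def derive_bank(
    meals: Sequence[MealRecord],
    refs: ReferenceIntakes,
    food_groups: Mapping[str, str],
    config: Mapping,
    seed: int | None = None,
) -> MealBank:
    """Condense typed diary meals into a generic-meal bank.

    ``config`` keys:

    ``k``
        mapping meal-type value -> cluster count, or a single int applied to
        every type; values may also be ``[lo, hi]`` ranges handed to
        :func:`select_k`.
    ``weighted_profiles``
        optional bool (default False): weight the generic per-100 g profile
        by member meal weight instead of the plain mean.

    Every meal must already carry a ``meal_type``.
    """
    untyped = [m.meal_id for m in meals if m.meal_type is None]
    if untyped:
        raise ValueError(f"meals without a type: {untyped[:5]}")
    weighted = bool(config.get("weighted_profiles", False))
    k_conf = config.get("k", {})
    generic_meals: list[GenericMeal] = []
    by_type: dict[MealType, list[MealRecord]] = {}
    for m in meals:
        by_type.setdefault(m.meal_type, []).append(m)
    for mtype in sorted(by_type, key=lambda t: t.value):
        members = by_type[mtype]
        try:
            if isinstance(k_conf, int):
                k_spec = k_conf
            else:
                k_spec = k_conf.get(mtype.value, k_conf.get("default", 1))
            if len(members) == 1:
                k, labels = 1, np.zeros(1, dtype=int)
                clusters = {0: members}
                medoid_of = {0: members[0]}
            else:
                matrix, _ = build_features(members, refs, food_groups)
                if isinstance(k_spec, (list, tuple)):
                    k = select_k(matrix, range(int(k_spec[0]), int(k_spec[1]) + 1), seed)
                else:
                    k = int(k_spec)
                res = pam(matrix, k, seed)
                clusters = {}
                medoid_of = {}
                for med in res.medoids:
                    rows = [i for i, lab in enumerate(res.labels) if lab == med]
                    clusters[med] = [members[i] for i in rows]
                    medoid_of[med] = members[med]
            for ci, med in enumerate(sorted(clusters), start=1):
                club = clusters[med]
                if weighted:
                    total = sum(m.total_weight_g for m in club)
                    acc: dict[str, float] = {}
                    for m in club:
                        for key in m.profile_per100g.keys():
                            acc[key] = acc.get(key, 0.0) + (
                                m.profile_per100g[key] * m.total_weight_g / total
                            )
                    profile = NutrientVector(acc, Basis.PER_100G)
                else:
                    keys = set()
                    for m in club:
                        keys |= set(m.profile_per100g.keys())
                    profile = NutrientVector(
                        {
                            key: sum(m.profile_per100g[key] for m in club) / len(club)
                            for key in keys
                        },
                        Basis.PER_100G,
                    )
                generic_meals.append(
                    GenericMeal(
                        id=f"{mtype.value}_{ci}",
                        meal_type=mtype,
                        profile_per100g=profile,
                        portion_weights_g=septile_portions(
                            [m.total_weight_g for m in club]
                        ),
                        member_meal_ids=[m.meal_id for m in club],
                        medoid_meal_id=medoid_of[med].meal_id,
                    )
                )
        except Exception as exc:
            raise RuntimeError(f"bank derivation failed for meal type {mtype.value!r}") from exc
    provenance = {
        "config_hash": _config_hash(dict(config)),
        "seed": seed,
        "n_input_meals": len(meals),
        "source": str(config.get("source", "unspecified")),
    }
    return MealBank(generic_meals, provenance)
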