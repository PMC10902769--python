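"""Nutrient Rich Foods profiling score (9.3 variant).

The score is evaluated on a per-100 kcal basis: the sum of capped percent
daily values of nine encouraged nutrients minus the (uncapped) percent
maximal reference values of three limited nutrients.  It is the nutrient
feature the meal-bank derivation clusters on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .nutrients import Basis, NutrientVector

logger = logging.getLogger(__name__)

__all__ = ["ReferenceIntakes", "nrf93", "DEFAULT_DV", "DEFAULT_MRV"]

#: Daily reference values for the nine encouraged nutrients (editable config;
#: standard published NRF9.3 reference amounts).
DEFAULT_DV: dict[str, float] = {
    "protein_g": 50.0,
    "fiber_g": 25.0,
    "vitamin_a_ug": 800.0,
    "vitamin_c_mg": 60.0,
    "vitamin_e_mg": 20.0,
    "calcium_mg": 1000.0,
    "iron_mg": 18.0,
    "potassium_mg": 3500.0,
    "magnesium_mg": 400.0,
}

#: Maximal reference values for the three limited nutrients.  ``sugar_g`` is
#: total sugars standing in for added sugar (most composition tables lack an
#: added-sugar field); see ``ReferenceIntakes.total_sugar_substitution``.
DEFAULT_MRV: dict[str, float] = {
    "saturated_fat_g": 20.0,
    "sugar_g": 50.0,
    "sodium_mg": 2400.0,
}


@dataclass(frozen=True)
class ReferenceIntakes:
    """Reference values configuring the NRF9.3 score.

    Exactly 9 encouraged (``dv``) and 3 limited (``mrv``) entries are
    required; all reference values must be positive.
    """

    dv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DV))
    mrv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MRV))
    cap_percent: float = 100.0
    total_sugar_substitution: bool = True

    def __post_init__(self) -> None:
        if len(self.dv) != 9:
            raise ValueError(f"NRF9.3 requires 9 encouraged nutrients, got {len(self.dv)}")
        if len(self.mrv) != 3:
            raise ValueError(f"NRF9.3 requires 3 limited nutrients, got {len(self.mrv)}")
        for name, ref in {**self.dv, **self.mrv}.items():
            if ref <= 0:
                raise ValueError(f"reference value for {name!r} must be > 0")
        if self.cap_percent <= 0:
            raise ValueError("cap_percent must be > 0")
        if self.total_sugar_substitution and "sugar_g" in self.mrv:
            logger.debug("NRF9.3 limited-sugar term uses total sugars")

    @classmethod
    def default(cls) -> "ReferenceIntakes":
        return cls()


def nrf93(
    profile: NutrientVector, refs: ReferenceIntakes | None = None
) -> float:
    """NRF9.3 score of a per-100 g profile, computed per 100 kcal.

    ``score = sum_i min(cap, 100 * a_i / dv_i) - sum_j 100 * a_j / mrv_j``
    where amounts ``a`` are first rescaled from per-100 g to per-100 kcal
    using the profile's own energy density.  Missing nutrients contribute 0.

    Raises
    ------
    ValueError
        If the profile's energy is not positive (score undefined).
    """
    if refs is None:
        refs = ReferenceIntakes.default()
    if profile.basis is not Basis.PER_100G:
        raise ValueError("nrf93 expects a per_100g profile")
    energy = profile["energy_kcal"]
    if energy <= 0:
        raise ValueError("nrf93 undefined for zero-energy profile")
    to_per100kcal = 100.0 / energy
    score = 0.0
    for key, dv in refs.dv.items():
        pct = 100.0 * profile[key] * to_per100kcal / dv
        score += min(refs.cap_percent, pct)
    for key, mrv in refs.mrv.items():
        score -= 100.0 * profile[key] * to_per100kcal / mrv
    return score
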