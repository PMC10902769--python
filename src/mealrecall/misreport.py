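"""Energy-intake plausibility screening.

Predicts basal metabolic rate (BMR) from anthropometry using age/sex-banded
linear equations, then classifies the reported-energy to BMR ratio against
fixed under/over-reporting cutoffs (defaults 0.96 and 2.49).  Screening is
advisory: it produces flags, never drops participants by itself.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Participant",
    "BmrRow",
    "BmrCoefficients",
    "ReportingStatus",
    "KCAL_PER_MJ",
    "bmr",
    "classify_misreporter",
    "screen_cohort",
]

KCAL_PER_MJ = 239.005736

UNDER_CUTOFF_DEFAULT = 0.96
OVER_CUTOFF_DEFAULT = 2.49


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class ReportingStatus(str, Enum):
    UNDER = "under"
    PLAUSIBLE = "plausible"
    OVER = "over"


@dataclass(frozen=True)
class Participant:
    id: str
    sex: Sex
    age_years: float
    weight_kg: float
    height_m: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.age_years <= 0 or self.weight_kg <= 0:
            raise ValueError("age and weight must be > 0")
        if not 18 <= self.age_years <= 110:
            logger.warning("participant %s: age %.1f outside 18-110", self.id, self.age_years)
        if not 25 <= self.weight_kg <= 300:
            logger.warning("participant %s: weight %.1f outside 25-300 kg", self.id, self.weight_kg)
        if self.height_m is not None and not 1.2 <= self.height_m <= 2.3:
            logger.warning("participant %s: height %.2f outside 1.2-2.3 m", self.id, self.height_m)


@dataclass(frozen=True)
class BmrRow:
    sex: Sex
    age_lo: float
    age_hi: float
    a_weight: float
    b_height: float
    c_const: float
    unit: str  # MJ_per_day | kcal_per_day

    def covers(self, sex: Sex, age: float) -> bool:
        return self.sex is sex and self.age_lo <= age < self.age_hi


@dataclass(frozen=True)
class BmrCoefficients:
    rows: tuple[BmrRow, ...]

    def __post_init__(self) -> None:
        # age bands per sex must not overlap
        by_sex: dict[Sex, list[BmrRow]] = {}
        for row in self.rows:
            by_sex.setdefault(row.sex, []).append(row)
        for sex, rows in by_sex.items():
            rows = sorted(rows, key=lambda r: r.age_lo)
            for a, b in zip(rows, rows[1:]):
                if b.age_lo < a.age_hi:
                    raise ValueError(f"overlapping age bands for sex {sex.value}")

    @classmethod
    def default(cls, variant: str = "weight_only") -> "BmrCoefficients":
        """Load the packaged coefficient table (weight-only by default).

        Self-reported height is noisier than self-reported weight, hence the
        weight-only default; pass ``variant='weight_height'`` for the
        weight-and-height equations.
        """
        path = resources.files("mealrecall.data") / "bmr_coefficients.csv"
        rows = []
        with path.open() as fh:
            for rec in csv.DictReader(fh):
                if rec["variant"] != variant:
                    continue
                rows.append(
                    BmrRow(
                        sex=Sex(rec["sex"]),
                        age_lo=float(rec["age_lo"]),
                        age_hi=float(rec["age_hi"]),
                        a_weight=float(rec["a_weight"]),
                        b_height=float(rec["b_height"]),
                        c_const=float(rec["c_const"]),
                        unit=rec["unit"],
                    )
                )
        if not rows:
            raise ValueError(f"no coefficient rows for variant {variant!r}")
        return cls(tuple(rows))


def bmr(p: Participant, coeffs: BmrCoefficients | None = None) -> float:
    """Predicted basal metabolic rate in kcal/day.

    ``a * weight_kg + b * height_m + c`` from the covering (sex, age) row,
    converted from MJ/day if necessary (1 MJ = 239.005736 kcal).

    Raises
    ------
    LookupError
        No coefficient row covers the participant's sex and age.
    """
    if coeffs is None:
        coeffs = BmrCoefficients.default()
    # top band treated as closed on the right
    sex_rows = [r for r in coeffs.rows if r.sex is p.sex]
    if not sex_rows:
        raise LookupError(f"no BMR coefficient rows for sex={p.sex.value}")
    max_hi = max(r.age_hi for r in sex_rows)
    for row in coeffs.rows:
        if row.covers(p.sex, p.age_years) or (
            row.sex is p.sex and p.age_years == row.age_hi == max_hi
        ):
            height = p.height_m if p.height_m is not None else 0.0
            if row.b_height != 0 and p.height_m is None:
                raise ValueError(f"participant {p.id}: height required by the BMR equation")
            value = row.a_weight * p.weight_kg + row.b_height * height + row.c_const
            if row.unit == "MJ_per_day":
                value *= KCAL_PER_MJ
            elif row.unit != "kcal_per_day":
                raise ValueError(f"unknown BMR unit {row.unit!r}")
            return value
    raise LookupError(
        f"no BMR coefficient row covers sex={p.sex.value}, age={p.age_years}"
    )


def classify_misreporter(
    ei_kcal: float,
    bmr_kcal: float,
    under_cutoff: float = UNDER_CUTOFF_DEFAULT,
    over_cutoff: float = OVER_CUTOFF_DEFAULT,
) -> tuple[ReportingStatus, float]:
    """Goldberg-style screen on the EI:BMR ratio.

    ``ratio < under_cutoff`` -> under-reporting, ``ratio > over_cutoff`` ->
    over-reporting, otherwise plausible (both boundaries count as plausible).
    Returns the status together with the ratio.
    """
    if bmr_kcal <= 0:
        raise ValueError("BMR must be > 0")
    ratio = ei_kcal / bmr_kcal
    if ratio < under_cutoff:
        return ReportingStatus.UNDER, ratio
    if ratio > over_cutoff:
        return ReportingStatus.OVER, ratio
    return ReportingStatus.PLAUSIBLE, ratio


def screen_cohort(
    participants: list[Participant],
    energy_kcal: dict[str, float],
    coeffs: BmrCoefficients | None = None,
    under_cutoff: float = UNDER_CUTOFF_DEFAULT,
    over_cutoff: float = OVER_CUTOFF_DEFAULT,
) -> pd.DataFrame:
    """Screen a cohort; returns id, bmr_kcal, ei_kcal, ratio, status."""
    if coeffs is None:
        coeffs = BmrCoefficients.default()
    records = []
    for p in participants:
        if p.id not in energy_kcal:
            raise KeyError(f"no energy intake for participant {p.id!r}")
        b = bmr(p, coeffs)
        status, ratio = classify_misreporter(energy_kcal[p.id], b, under_cutoff, over_cutoff)
        records.append(
            {
                "participant_id": p.id,
                "bmr_kcal": b,
                "ei_kcal": energy_kcal[p.id],
                "ei_bmr_ratio": ratio,
                "status": status.value,
            }
        )
    return pd.DataFrame.from_records(records)
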