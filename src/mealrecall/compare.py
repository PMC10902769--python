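"""Paired-method comparison battery.

Everything needed to compare daily nutrient intakes estimated by two
instruments on the same participants: Wilcoxon signed-rank tests with
effect sizes, Bland-Altman limits of agreement, Spearman rank correlation,
cross-classification of quartiles, guideline-category agreement and the
percentage-difference summaries.  Method A is the reference instrument;
Bland-Altman differences are A - B while percentage differences are
(B - A) / A — the two conventions the result tables use.

Quantiles are linear-interpolation (type-7) throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .nutrients import (
    MACRO_TEI_MAP,
    EnergyFactors,
    NutrientVector,
    percent_tei,
    salt_from_sodium,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "effect_size",
    "bland_altman",
    "spearman",
    "cross_classify_quartiles",
    "GuidelineEntry",
    "GuidelineTable",
    "classify_guidelines",
    "guideline_agreement",
    "percent_difference",
    "summarize_differences",
    "add_percent_tei_columns",
    "run_comparison",
]


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    z: float  # normal-approximation Z (tie + continuity corrected)
    n_nonzero: int
    n_total: int
    exact: bool


def _exact_wplus_counts(m: int) -> np.ndarray:
    """Counts of sign assignments per W+ value for ranks 1..m (2^m total)."""
    max_sum = m * (m + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, m + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded; |differences| are ranked with midranks
    for ties.  The exact sign-assignment distribution is used when the
    non-zero count is <= *exact_max_n* and there are no tied |differences|;
    otherwise a normal approximation with tie correction and a continuity
    correction.  The corrected Z is always computed (the effect size needs
    it).

    Raises
    ------
    ValueError
        If every difference is zero (test undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    n_total = d.size
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    mu = m * (m + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    sd = math.sqrt(var) if var > 0 else 0.0
    num = w_plus - mu
    if sd == 0:
        z = 0.0
    elif abs(num) <= 0.5:
        z = 0.0
    else:
        z = (num - math.copysign(0.5, num)) / sd

    has_ties = bool((tie_counts > 1).any())
    if m <= exact_max_n and not has_ties:
        counts = _exact_wplus_counts(m)
        total = counts.sum()
        w_int = int(round(w_plus))
        p_le = counts[: w_int + 1].sum() / total
        p_ge = counts[w_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        exact = True
    else:
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        exact = False
    return WilcoxonResult(w_plus, float(p), float(z), m, n_total, exact)


EFFECT_CUTOFFS = (0.1, 0.3, 0.5)


def effect_size(z: float, n_pairs: int) -> tuple[float, str]:
    """Wilcoxon effect size ``r = |Z| / sqrt(n)`` with magnitude label.

    Labels: r < 0.1 negligible, 0.1 <= r < 0.3 small, 0.3 <= r < 0.5
    moderate, r >= 0.5 large.  *n_pairs* is the total number of pairs
    entering the test.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    r = abs(z) / math.sqrt(n_pairs)
    if r < EFFECT_CUTOFFS[0]:
        label = "negligible"
    elif r < EFFECT_CUTOFFS[1]:
        label = "small"
    elif r < EFFECT_CUTOFFS[2]:
        label = "moderate"
    else:
        label = "large"
    return r, label


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def bland_altman(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, float, int, float]:
    """Bland-Altman agreement of paired measurements (differences = A - B).

    Returns ``(mean_diff, loa_lo, loa_hi, n_within, prop_within)`` with
    limits of agreement at mean +/- 1.96 * sample SD (ddof=1) and the
    within-count taken on the closed interval.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("bland_altman requires >= 2 pairs of equal length")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = int(((d >= lo) & (d <= hi)).sum())
    return mean, lo, hi, within, within / d.size


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

SPEARMAN_CUTOFFS = (0.20, 0.50)


def spearman(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, str]:
    """Spearman rank correlation: Pearson on midranks, t-approximation P.

    Labels: |not applied to| magnitude — rho < 0.20 poor, 0.20 <= rho < 0.50
    acceptable, rho >= 0.50 good (as signed values; negative rho is poor).

    Raises
    ------
    ValueError
        Fewer than 3 pairs or a constant column (correlation undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("spearman requires >= 3 pairs of equal length")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("spearman undefined for a constant sample")
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    rho = float(np.corrcoef(ra, rb)[0, 1])
    n = a.size
    rho_c = max(min(rho, 1.0), -1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
    else:
        t = rho_c * math.sqrt((n - 2) / (1 - rho_c**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    if rho < SPEARMAN_CUTOFFS[0]:
        label = "poor"
    elif rho < SPEARMAN_CUTOFFS[1]:
        label = "acceptable"
    else:
        label = "good"
    return rho, p, label


# ---------------------------------------------------------------------------
# Cross-classification of quartiles
# ---------------------------------------------------------------------------

def _quartile_bins(values: np.ndarray) -> np.ndarray:
    """Quartile index 1..4 per value; cut points are type-7 quantiles and a
    value equal to a cut point falls in the lower quartile."""
    cuts = np.quantile(values, [0.25, 0.5, 0.75])
    return 1 + (values[:, None] > cuts[None, :]).sum(axis=1)


def cross_classify_quartiles(
    a: Sequence[float], b: Sequence[float]
) -> dict[str, int]:
    """Agreement of quartile placement between two methods.

    Returns counts keyed ``exact`` (same quartile), ``exact_plus_adjacent``
    (<= 1 apart), ``disagreement`` (exactly 2 apart) and ``extreme``
    (3 apart).  ``exact_plus_adjacent`` includes the exact matches, mirroring
    how agreement tables report it.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 4:
        raise ValueError("cross-classification requires >= 4 pairs of equal length")
    qa = _quartile_bins(a)
    qb = _quartile_bins(b)
    gap = np.abs(qa - qb)
    return {
        "exact": int((gap == 0).sum()),
        "exact_plus_adjacent": int((gap <= 1).sum()),
        "disagreement": int((gap == 2).sum()),
        "extreme": int((gap == 3).sum()),
    }


# ---------------------------------------------------------------------------
# Guideline categorisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuidelineEntry:
    """One nutrient's guideline: cut points, labels and the evaluation unit.

    ``unit`` is one of ``absolute`` (the intake column as-is), ``percent_tei``
    (requires ``macro``), ``g_per_kg_bw`` (requires participant weight) or
    ``salt_g`` (sodium converted to salt equivalent).  Boundary values belong
    to the lower category.
    """

    nutrient: str
    unit: str
    cutpoints: tuple[float, ...]
    labels: tuple[str, ...]
    macro: str | None = None

    def __post_init__(self) -> None:
        if self.unit not in {"absolute", "percent_tei", "g_per_kg_bw", "salt_g"}:
            raise ValueError(f"unknown guideline unit {self.unit!r}")
        if list(self.cutpoints) != sorted(set(self.cutpoints)):
            raise ValueError("cut points must be strictly increasing")
        if len(self.labels) != len(self.cutpoints) + 1:
            raise ValueError("label count must be cut point count + 1")
        if self.unit == "percent_tei" and self.macro not in MACRO_TEI_MAP:
            raise ValueError(f"percent_tei entries need a macro in {sorted(MACRO_TEI_MAP)}")


@dataclass(frozen=True)
class GuidelineTable:
    entries: Mapping[str, GuidelineEntry]

    @classmethod
    def from_dict(cls, raw: Mapping) -> "GuidelineTable":
        entries = {}
        for name, spec in raw.items():
            if name.startswith("_"):
                continue
            entries[name] = GuidelineEntry(
                nutrient=spec["nutrient"],
                unit=spec.get("unit", "absolute"),
                cutpoints=tuple(float(c) for c in spec["cutpoints"]),
                labels=tuple(spec["labels"]),
                macro=spec.get("macro"),
            )
        return cls(entries)


def classify_guidelines(
    day: NutrientVector | Mapping[str, float],
    entry: GuidelineEntry,
    weight_kg: float | None = None,
    factors: EnergyFactors = EnergyFactors(),
) -> str:
    """Categorise one participant-day's intake against a guideline entry."""
    get = day.__getitem__ if isinstance(day, NutrientVector) else (
        lambda k: float(day.get(k, 0.0))
    )
    if entry.unit == "absolute":
        value = get(entry.nutrient)
    elif entry.unit == "percent_tei":
        vec = day if isinstance(day, NutrientVector) else NutrientVector(
            dict(day), "per_day"
        )
        value = percent_tei(vec, factors)[entry.macro]
    elif entry.unit == "g_per_kg_bw":
        if weight_kg is None or weight_kg <= 0:
            raise ValueError(f"guideline for {entry.nutrient} needs participant weight")
        value = get(entry.nutrient) / weight_kg
    else:  # salt_g
        value = salt_from_sodium(get("sodium_mg"))
    idx = int(sum(value > c for c in entry.cutpoints))
    return entry.labels[idx]


def guideline_agreement(
    categories_a: Sequence[str], categories_b: Sequence[str]
) -> tuple[int, float]:
    """Count and proportion of participants placed in the same category."""
    if len(categories_a) != len(categories_b) or not categories_a:
        raise ValueError("category lists must be non-empty and of equal length")
    same = sum(x == y for x, y in zip(categories_a, categories_b))
    return same, same / len(categories_a)


# ---------------------------------------------------------------------------
# Percentage differences
# ---------------------------------------------------------------------------

def percent_difference(median_a: float, median_b: float) -> float:
    """Signed percent difference of B relative to A: 100 * (B - A) / A."""
    if median_a <= 0:
        raise ValueError("reference median must be > 0")
    return 100.0 * (median_b - median_a) / median_a


def summarize_differences(pct_list: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles of |percent differences| (type-7 quantiles)."""
    if len(pct_list) == 0:
        raise ValueError("summarize_differences requires at least one value")
    x = np.abs(np.asarray(pct_list, dtype=float))
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def add_percent_tei_columns(
    df: pd.DataFrame,
    macros: Iterable[str] = (
        "protein",
        "carbohydrate",
        "sugar",
        "total_fat",
        "saturated_fat",
        "monounsaturated_fat",
        "polyunsaturated_fat",
    ),
    factors: EnergyFactors = EnergyFactors(),
) -> pd.DataFrame:
    """Append ``<macro>_pct_tei`` columns computed row-wise from the gram
    columns and ``energy_kcal``."""
    out = df.copy()
    for macro in macros:
        gram_key, factor_name = MACRO_TEI_MAP[macro]
        out[f"{macro}_pct_tei"] = (
            100.0 * df[gram_key] * getattr(factors, factor_name) / df["energy_kcal"]
        )
    return out


@dataclass
class ComparisonRow:
    nutrient: str
    n: int
    median_a: float
    q1_a: float
    q3_a: float
    median_b: float
    q1_b: float
    q3_b: float
    pct_diff: float
    wilcoxon_p: float
    effect_r: float
    effect_label: str
    ba_mean_diff: float
    ba_loa_lo: float
    ba_loa_hi: float
    n_within_loa: int
    prop_within_loa: float
    spearman_rho: float
    spearman_p: float
    spearman_label: str
    q_exact: int
    q_exact_plus_adjacent: int
    q_disagreement: int
    q_extreme: int


def run_comparison(
    intakes_a: pd.DataFrame,
    intakes_b: pd.DataFrame,
    nutrients: Sequence[str] | None = None,
    effect_denominator: str = "total",
) -> tuple[pd.DataFrame, dict]:
    """Full per-nutrient comparison of two participant x nutrient tables.

    Both tables are indexed by participant id with one column per nutrient
    variable.  Method A is the reference.  Returns a results table (one
    :class:`ComparisonRow` per nutrient) and a summary block with the
    median/IQR of |percent difference|, effect-label counts and the number
    of significant correlations.

    Raises
    ------
    ValueError
        If the participant sets differ (the offending ids are listed).
    """
    only_a = sorted(set(intakes_a.index) - set(intakes_b.index))
    only_b = sorted(set(intakes_b.index) - set(intakes_a.index))
    if only_a or only_b:
        raise ValueError(
            f"participant sets differ: only in A={only_a[:10]}, only in B={only_b[:10]}"
        )
    intakes_b = intakes_b.loc[intakes_a.index]
    if nutrients is None:
        nutrients = [c for c in intakes_a.columns if c in intakes_b.columns]
    if effect_denominator not in {"total", "nonzero"}:
        raise ValueError("effect_denominator must be 'total' or 'nonzero'")

    rows: list[ComparisonRow] = []
    for nut in nutrients:
        a = intakes_a[nut].to_numpy(dtype=float)
        b = intakes_b[nut].to_numpy(dtype=float)
        if a.size < 3:
            raise ValueError(f"need >= 3 pairs, got {a.size} for {nut}")
        q1a, med_a, q3a = np.quantile(a, [0.25, 0.5, 0.75])
        q1b, med_b, q3b = np.quantile(b, [0.25, 0.5, 0.75])
        pct = percent_difference(med_a, med_b) if med_a > 0 else float("nan")
        try:
            wres = wilcoxon_signed_rank(a, b)
            denom = wres.n_total if effect_denominator == "total" else wres.n_nonzero
            r, label = effect_size(wres.z, denom)
            wp = wres.p_value
        except ValueError:
            # all differences zero: perfect agreement
            wp, r, label = 1.0, 0.0, "negligible"
        mean_d, lo, hi, n_within, prop_within = bland_altman(a, b)
        try:
            rho, sp, slabel = spearman(a, b)
        except ValueError:
            rho, sp, slabel = float("nan"), float("nan"), "undefined"
        quart = cross_classify_quartiles(a, b)
        rows.append(
            ComparisonRow(
                nutrient=nut,
                n=a.size,
                median_a=float(med_a),
                q1_a=float(q1a),
                q3_a=float(q3a),
                median_b=float(med_b),
                q1_b=float(q1b),
                q3_b=float(q3b),
                pct_diff=float(pct),
                wilcoxon_p=wp,
                effect_r=r,
                effect_label=label,
                ba_mean_diff=mean_d,
                ba_loa_lo=lo,
                ba_loa_hi=hi,
                n_within_loa=n_within,
                prop_within_loa=prop_within,
                spearman_rho=rho,
                spearman_p=sp,
                spearman_label=slabel,
                q_exact=quart["exact"],
                q_exact_plus_adjacent=quart["exact_plus_adjacent"],
                q_disagreement=quart["disagreement"],
                q_extreme=quart["extreme"],
            )
        )
    result = pd.DataFrame([vars(r) for r in rows]).set_index("nutrient")
    pct_vals = result["pct_diff"].dropna().to_list()
    med, q1, q3 = summarize_differences(pct_vals) if pct_vals else (float("nan"),) * 3
    summary = {
        "n_nutrients": len(rows),
        "abs_pct_diff_median": med,
        "abs_pct_diff_q1": q1,
        "abs_pct_diff_q3": q3,
        "effect_label_counts": result["effect_label"].value_counts().to_dict(),
        "n_significant_correlations": int((result["spearman_p"] < 0.05).sum()),
        "n_significant_wilcoxon": int((result["wilcoxon_p"] < 0.05).sum()),
    }
    return result, summary
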