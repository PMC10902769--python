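"""File formats: CSV tables, JSON banks/responses, provenance headers.

CSV outputs carry ``# key: value`` provenance comment lines (tool version,
config hash, seed) which readers skip; JSON outputs carry a ``_provenance``
object.  Readers validate schemas eagerly and report offending columns, ids
and line numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .derive import GenericMeal, MealBank
from .nutrients import Basis, MealRecord, MealType, NutrientVector
from .recall import RecallResponse, Relative, Slot

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_foods",
    "write_foods",
    "read_diary",
    "write_diary",
    "read_bank",
    "write_bank",
    "read_responses",
    "write_responses",
    "read_intakes",
    "write_intakes",
    "config_hash",
]


class SchemaError(ValueError):
    """Input file violates its schema; message carries file/line context."""


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _provenance(extra: Mapping | None = None) -> dict:
    meta = {"tool": f"mealrecall {__version__}"}
    if extra:
        meta.update(extra)
    return meta


def _write_csv(df: pd.DataFrame, path, meta: Mapping | None, index: bool) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in _provenance(meta).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=index)


def _read_csv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    return pd.read_csv(path, comment="#", **kwargs)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


# -- foods ------------------------------------------------------------------

def read_foods(path) -> pd.DataFrame:
    """Food composition table: food_id, food_group, one column per nutrient
    (per 100 g).  Duplicate ids are rejected by name."""
    df = _read_csv(path)
    _require_columns(df, ["food_id", "food_group"], path)
    dupes = df["food_id"][df["food_id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"{path}: duplicated food_id(s) {sorted(set(dupes))}")
    nutrient_cols = [c for c in df.columns if c not in ("food_id", "food_group")]
    bad = df[nutrient_cols].select_dtypes(exclude="number").columns.tolist()
    if bad:
        raise SchemaError(f"{path}: non-numeric nutrient column(s) {bad}")
    if (df[nutrient_cols] < 0).any().any():
        raise SchemaError(f"{path}: negative nutrient amounts present")
    return df


def write_foods(df: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    _write_csv(df, path, meta, index=False)


# -- diary ------------------------------------------------------------------

DIARY_COLUMNS = ["participant_id", "day", "occasion_label", "meal_type", "food_id", "weight_g"]


def write_diary(meals: Sequence[MealRecord], path, meta: Mapping | None = None) -> None:
    rows = []
    for m in meals:
        for fid, w in m.foods:
            rows.append(
                {
                    "participant_id": m.participant_id,
                    "day": m.day_index,
                    "occasion_label": m.occasion_label,
                    "meal_type": m.meal_type.value if m.meal_type else "",
                    "food_id": fid,
                    "weight_g": w,
                }
            )
    _write_csv(pd.DataFrame(rows, columns=DIARY_COLUMNS), path, meta, index=False)


def read_diary(path, foods: pd.DataFrame) -> list[MealRecord]:
    """Assemble meal records from the long diary format.

    Rows sharing (participant_id, day, occasion_label) form one meal; the
    per-100 g profile is rebuilt from the food composition table.
    """
    df = _read_csv(path)
    _require_columns(df, ["participant_id", "day", "occasion_label", "food_id", "weight_g"], path)
    nutrient_cols = [c for c in foods.columns if c not in ("food_id", "food_group")]
    profiles = {
        rec["food_id"]: NutrientVector(
            {c: float(rec[c]) for c in nutrient_cols}, Basis.PER_100G
        )
        for rec in foods.to_dict("records")
    }
    unknown = sorted(set(df["food_id"]) - set(profiles))
    if unknown:
        raise SchemaError(f"{path}: food ids absent from the composition table: {unknown[:10]}")
    if (df["weight_g"] <= 0).any():
        line = int(df.index[df["weight_g"] <= 0][0]) + 2
        raise SchemaError(f"{path}: non-positive weight_g near data row {line}")
    meals = []
    has_type = "meal_type" in df.columns
    for (pid, day, label), grp in df.groupby(
        ["participant_id", "day", "occasion_label"], sort=False
    ):
        mtype = None
        if has_type:
            raw = str(grp["meal_type"].iloc[0])
            if raw and raw.lower() != "nan":
                mtype = MealType(raw)
        items = [
            (rec["food_id"], float(rec["weight_g"]), profiles[rec["food_id"]])
            for rec in grp.to_dict("records")
        ]
        meals.append(
            MealRecord.from_foods(str(pid), int(day), str(label), items, meal_type=mtype)
        )
    return meals


# -- meal bank --------------------------------------------------------------

def write_bank(bank: MealBank, path, meta: Mapping | None = None) -> None:
    payload = {
        "_provenance": _provenance({**bank.provenance, **(meta or {})}),
        "generic_meals": [
            {
                "id": gm.id,
                "meal_type": gm.meal_type.value,
                "profile_per100g": gm.profile_per100g.as_dict(),
                "portion_weights_g": gm.portion_weights_g,
                "member_count": gm.member_count,
                "member_meal_ids": gm.member_meal_ids,
                "medoid_meal_id": gm.medoid_meal_id,
            }
            for gm in bank.generic_meals
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_bank(path) -> MealBank:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    try:
        meals = [
            GenericMeal(
                id=raw["id"],
                meal_type=MealType(raw["meal_type"]),
                profile_per100g=NutrientVector(raw["profile_per100g"], Basis.PER_100G),
                portion_weights_g=[float(w) for w in raw["portion_weights_g"]],
                member_meal_ids=list(raw.get("member_meal_ids") or [raw["medoid_meal_id"]]),
                medoid_meal_id=raw["medoid_meal_id"],
            )
            for raw in payload["generic_meals"]
        ]
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed bank ({exc})") from exc
    return MealBank(meals, provenance=payload.get("_provenance", {}))


# -- recall responses -------------------------------------------------------

def write_responses(
    responses: Mapping[tuple[str, int], Sequence[RecallResponse]] | Sequence[RecallResponse],
    path,
    meta: Mapping | None = None,
) -> None:
    if isinstance(responses, Mapping):
        flat = [
            {"day": day, **_response_dict(r)}
            for (pid, day), rs in responses.items()
            for r in rs
        ]
    else:
        flat = [_response_dict(r) for r in responses]
    payload = {"_provenance": _provenance(meta), "responses": flat}
    Path(path).write_text(json.dumps(payload, indent=2))


def _response_dict(r: RecallResponse) -> dict:
    return {
        "participant_id": r.participant_id,
        "slot": r.slot.value,
        "generic_meal_id": r.generic_meal_id,
        "free_text": r.free_text,
        "image_index": r.image_index,
        "relative": r.relative.value if r.relative else None,
        "count": r.count,
    }


def read_responses(path) -> list[tuple[int, RecallResponse]]:
    """Responses as ``(day, RecallResponse)`` pairs (day defaults to 1)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    payload = json.loads(path.read_text())
    raw_list = payload["responses"] if isinstance(payload, dict) else payload
    out = []
    for i, raw in enumerate(raw_list):
        try:
            out.append(
                (
                    int(raw.get("day", 1)),
                    RecallResponse(
                        participant_id=raw["participant_id"],
                        slot=Slot(raw["slot"]),
                        generic_meal_id=raw.get("generic_meal_id"),
                        free_text=raw.get("free_text"),
                        image_index=raw.get("image_index"),
                        relative=Relative(raw["relative"]) if raw.get("relative") else None,
                        count=raw.get("count"),
                    ),
                )
            )
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"{path}: bad response at entry {i}: {exc}") from exc
    return out


# -- intake tables ----------------------------------------------------------

def write_intakes(df: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    """Participant x nutrient intake table (index = participant_id)."""
    _write_csv(df, path, meta, index=True)


def read_intakes(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ["participant_id"], path)
    dupes = df["participant_id"][df["participant_id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"{path}: duplicated participant_id(s) {sorted(set(dupes))}")
    return df.set_index("participant_id").sort_index()
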