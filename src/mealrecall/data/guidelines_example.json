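{
  "_comment": "Example guideline table. Cut points are editable placeholders on common European reference ranges; boundary values fall in the lower category.",
  "protein": {"nutrient": "protein_g", "unit": "g_per_kg_bw", "cutpoints": [0.8, 2.0], "labels": ["low", "adequate", "high"]},
  "carbohydrate": {"nutrient": "carbohydrate_g", "unit": "percent_tei", "macro": "carbohydrate", "cutpoints": [45.0, 60.0], "labels": ["low", "adequate", "high"]},
  "total_fat": {"nutrient": "fat_g", "unit": "percent_tei", "macro": "total_fat", "cutpoints": [20.0, 35.0], "labels": ["low", "adequate", "high"]},
  "monounsaturated_fat": {"nutrient": "monounsaturated_fat_g", "unit": "percent_tei", "macro": "monounsaturated_fat", "cutpoints": [10.0, 20.0], "labels": ["low", "adequate", "high"]},
  "polyunsaturated_fat": {"nutrient": "polyunsaturated_fat_g", "unit": "percent_tei", "macro": "polyunsaturated_fat", "cutpoints": [6.0, 11.0], "labels": ["low", "adequate", "high"]},
  "saturated_fat": {"nutrient": "saturated_fat_g", "unit": "percent_tei", "macro": "saturated_fat", "cutpoints": [10.0], "labels": ["adequate", "high"]},
  "salt": {"nutrient": "sodium_mg", "unit": "salt_g", "cutpoints": [6.0], "labels": ["adequate", "high"]},
  "fiber": {"nutrient": "fiber_g", "unit": "absolute", "cutpoints": [25.0], "labels": ["low", "adequate"]},
  "calcium": {"nutrient": "calcium_mg", "unit": "absolute", "cutpoints": [800.0, 2500.0], "labels": ["low", "adequate", "high"]},
  "iron": {"nutrient": "iron_mg", "unit": "absolute", "cutpoints": [11.0, 45.0], "labels": ["low", "adequate", "high"]},
  "folate": {"nutrient": "folate_ug", "unit": "absolute", "cutpoints": [330.0, 1000.0], "labels": ["low", "adequate", "high"]},
  "thiamin": {"nutrient": "thiamin_mg", "unit": "absolute", "cutpoints": [0.9], "labels": ["low", "adequate"]},
  "riboflavin": {"nutrient": "riboflavin_mg", "unit": "absolute", "cutpoints": [1.3], "labels": ["low", "adequate"]},
  "vitamin_c": {"nutrient": "vitamin_c_mg", "unit": "absolute", "cutpoints": [60.0, 2000.0], "labels": ["low", "adequate", "high"]}
}
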