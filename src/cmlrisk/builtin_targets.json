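{
  "schema_version": 1,
  "name": "table4",
  "description": "Published aggregate counts for a 95-patient imatinib-treated CML cohort: joint dichotomized risk-label patterns (Sokal, Hasford, EUTOS, ELTS; intermediate merged with low) split by MMR outcome, plus the per-system high-risk marginals under the alternative merge (intermediate with high).",
  "systems": ["SOKAL", "HASFORD", "EUTOS", "ELTS"],
  "combination_rows": [
    {"pattern": ["LOWISH", "LOWISH", "LOWISH", "LOWISH"], "n_mmr": 43, "n_no_mmr": 19},
    {"pattern": ["LOWISH", "LOWISH", "LOWISH", "HIGH"], "n_mmr": 5, "n_no_mmr": 2},
    {"pattern": ["LOWISH", "LOWISH", "HIGH", "LOWISH"], "n_mmr": 0, "n_no_mmr": 0},
    {"pattern": ["LOWISH", "LOWISH", "HIGH", "HIGH"], "n_mmr": 0, "n_no_mmr": 1},
    {"pattern": ["LOWISH", "HIGH", "LOWISH", "LOWISH"], "n_mmr": 0, "n_no_mmr": 0},
    {"pattern": ["LOWISH", "HIGH", "LOWISH", "HIGH"], "n_mmr": 0, "n_no_mmr": 0},
    {"pattern": ["LOWISH", "HIGH", "HIGH", "LOWISH"], "n_mmr": 0, "n_no_mmr": 0},
    {"pattern": ["LOWISH", "HIGH", "HIGH", "HIGH"], "n_mmr": 0, "n_no_mmr": 0},
    {"pattern": ["HIGH", "LOWISH", "LOWISH", "LOWISH"], "n_mmr": 7, "n_no_mmr": 5},
    {"pattern": ["HIGH", "LOWISH", "LOWISH", "HIGH"], "n_mmr": 0, "n_no_mmr": 1},
    {"pattern": ["HIGH", "LOWISH", "HIGH", "LOWISH"], "n_mmr": 1, "n_no_mmr": 1},
    {"pattern": ["HIGH", "LOWISH", "HIGH", "HIGH"], "n_mmr": 4, "n_no_mmr": 0},
    {"pattern": ["HIGH", "HIGH", "LOWISH", "LOWISH"], "n_mmr": 1, "n_no_mmr": 1},
    {"pattern": ["HIGH", "HIGH", "LOWISH", "HIGH"], "n_mmr": 0, "n_no_mmr": 1},
    {"pattern": ["HIGH", "HIGH", "HIGH", "LOWISH"], "n_mmr": 0, "n_no_mmr": 0},
    {"pattern": ["HIGH", "HIGH", "HIGH", "HIGH"], "n_mmr": 1, "n_no_mmr": 2}
  ],
  "merge_high_high_counts": {
    "SOKAL": {"n_mmr": 39, "n_no_mmr": 23},
    "HASFORD": {"n_mmr": 26, "n_no_mmr": 20},
    "EUTOS": {"n_mmr": 6, "n_no_mmr": 4},
    "ELTS": {"n_mmr": 23, "n_no_mmr": 19}
  }
}
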