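"""Synthetic cohort generation and aggregate-table reconstruction."""

import json
import math

import numpy as np
import pandas as pd
import pytest

import cmlrisk as cr
from cmlrisk.core import _find_patient

S = cr.ScoringSystem
L = cr.DichotomousLabel
G = cr.GroupingStrategy

TABLE1_MEDIANS = {
    "age_years": 40.21,
    "spleen_cm_bcm": 8.33,
    "platelets_10e9_L": 510.97,
    "blasts_pct": 1.50,
    "eosinophils_pct": 0.83,
    "basophils_pct": 1.32,
}


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = cr.CohortConfig(n_patients=200, seed=17)
        a, b = cr.generate_cohort(cfg), cr.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        c = cr.generate_cohort(cr.CohortConfig(n_patients=200, seed=18))
        assert not a.drop(columns="patient_id").equals(
            c.drop(columns="patient_id"))

    def test_sample_medians_match_reference_marginals(self):
        cohort = cr.generate_cohort(cr.CohortConfig(n_patients=10_000,
                                                    seed=101))
        for col, med in TABLE1_MEDIANS.items():
            assert cohort[col].median() == pytest.approx(med, rel=0.05), col

    def test_bounds_respected(self):
        cohort = cr.generate_cohort(cr.CohortConfig(n_patients=2000, seed=4))
        for col, spec in cr.CohortConfig(n_patients=1).variables.items():
            assert cohort[col].between(spec.lo, spec.hi).all(), col

    def test_zero_association_recovers_baseline_rate(self):
        n = 10_000
        cfg = cr.CohortConfig(n_patients=n, seed=23, association=0.0)
        rate = cr.generate_cohort(cfg).mmr_achieved.mean()
        p = cfg.baseline_mmr_rate
        assert abs(rate - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_positive_association_penalizes_high_risk(self):
        cohort = cr.generate_cohort(
            cr.CohortConfig(n_patients=10_000, seed=29, association=1.0))
        scored = cr.score_cohort(cohort)
        high = scored["sokal_cat"].eq("HIGH")
        assert cohort.mmr_achieved[high].mean() < \
            cohort.mmr_achieved[~high].mean()

    def test_logistic_slope_recovery(self):
        target = 1.0
        cohort = cr.generate_cohort(
            cr.CohortConfig(n_patients=10_000, seed=31, association=target))
        comp = cr.risk_composite(cr.score_cohort(cohort))
        _, slope, se = cr.fit_logistic_slope(
            comp, cohort.mmr_achieved.to_numpy())
        assert abs(slope - (-target)) < 3 * se

    def test_invalid_config_rejected(self):
        with pytest.raises(cr.ValidationError):
            cr.CohortConfig(n_patients=0)
        with pytest.raises(cr.ValidationError):
            cr.CohortConfig(n_patients=5, baseline_mmr_rate=1.5)
        with pytest.raises(cr.ValidationError):
            cr.VariableSpec(median=50, sd=1, lo=0, hi=40)


class TestTargetTables:
    def test_builtin_totals(self, builtin_targets):
        assert builtin_targets.total == 95
        mmr = sum(v[0] for v in builtin_targets.rows.values())
        assert mmr == 62

    def test_intermediate_needs_are_consistent(self, builtin_targets):
        # Merged-high minus pattern-derived high = intermediates to place.
        assert builtin_targets.intermediate_need(S.SOKAL) == (25, 12)
        assert builtin_targets.intermediate_need(S.HASFORD) == (24, 16)
        assert builtin_targets.intermediate_need(S.ELTS) == (13, 12)
        assert builtin_targets.intermediate_need(S.EUTOS) == (0, 0)

    def test_inconsistent_targets_rejected(self, builtin_targets):
        payload = json.loads(json.dumps({
            "combination_rows": [r.to_dict() for r in _rows(builtin_targets)],
            "merge_high_high_counts": {
                s.value: {"n_mmr": 0, "n_no_mmr": 0} for s in S},
        }))
        with pytest.raises(cr.ValidationError):
            cr.TargetTables.from_dict(payload)

    def test_missing_pattern_rejected(self):
        with pytest.raises(cr.ValidationError, match="16"):
            cr.TargetTables.from_dict({"combination_rows": [
                {"pattern": ["LOWISH"] * 4, "n_mmr": 1, "n_no_mmr": 0}]})


def _rows(targets):
    return [cr.CombinationRow(pattern=p, n_mmr=v[0], n_no_mmr=v[1])
            for p, v in targets.rows.items()]


class TestReconstruct:
    def test_round_trip_reproduces_targets_exactly(
            self, builtin_targets, reconstructed_scored):
        part = cr.partition(reconstructed_scored, G.LOW_INT_AS_LOW)
        for row in part.rows:
            want = builtin_targets.rows[row.pattern]
            assert (row.n_mmr, row.n_no_mmr) == want, row.pattern
        assert part.n_consensus == 65
        assert part.n_conflict == 30

    def test_alternative_merge_marginals_reproduced(
            self, builtin_targets, reconstructed_scored):
        for system in S:
            t = cr.build_contingency(reconstructed_scored, system,
                                     G.INT_HIGH_AS_HIGH)
            assert (t.n_high_mmr, t.n_high_no_mmr) == \
                builtin_targets.merge_high_high[system]

    def test_patients_verified_by_scoring(self, reconstructed):
        # Every emitted record must satisfy the baseline contract and the
        # schema; categories were already verified inside reconstruction.
        assert len(reconstructed) == 95
        assert list(reconstructed.columns) == cr.COHORT_COLUMNS
        cr.score_cohort(reconstructed)  # raises on any invalid record

    def test_deterministic_given_seed(self, builtin_targets):
        a = cr.reconstruct_cohort(builtin_targets, seed=5)
        b = cr.reconstruct_cohort(builtin_targets, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_single_row_target(self):
        rows = []
        for pattern in cr.label_patterns():
            n = 1 if pattern == (L.HIGH, L.LOWISH, L.LOWISH, L.LOWISH) else 0
            rows.append({"pattern": [p.value for p in pattern],
                         "n_mmr": n, "n_no_mmr": 0})
        targets = cr.TargetTables.from_dict({"combination_rows": rows})
        cohort = cr.reconstruct_cohort(targets, seed=6)
        assert len(cohort) == 1
        scored = cr.score_cohort(cohort)
        assert scored.loc[0, "sokal_cat"] == "HIGH"
        assert scored.loc[0, "hasford_cat"] in ("LOW", "INTERMEDIATE")

    def test_infeasible_pattern_names_the_pattern(self, monkeypatch):
        # Shrink the search box so a EUTOS-high patient cannot exist.
        import cmlrisk.core as core
        box = dict(core._SEARCH_BOX)
        box["spleen_cm_bcm"] = (0.0, 1.0)
        box["basophils_pct"] = (0.0, 1.0)
        monkeypatch.setattr(core, "_SEARCH_BOX", box)
        with pytest.raises(cr.InfeasiblePatternError, match="HIGH"):
            _find_patient((0, 0, 2, 0), seed=1, max_draws=1000,
                          de_restarts=1, de_maxiter=5)
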