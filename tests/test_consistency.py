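"""Dichotomization, contingency accuracy and consensus/conflict analysis."""

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pytest

import cmlrisk as cr
from conftest import make_patient, make_scored_frame, random_scored_frame

S = cr.ScoringSystem
C = cr.RiskCategory
L = cr.DichotomousLabel
G = cr.GroupingStrategy


class TestDichotomize:
    @pytest.mark.parametrize("cat, strategy, expected", [
        (C.LOW, G.LOW_INT_AS_LOW, L.LOWISH),
        (C.LOW, G.INT_HIGH_AS_HIGH, L.LOWISH),
        (C.INTERMEDIATE, G.LOW_INT_AS_LOW, L.LOWISH),
        (C.INTERMEDIATE, G.INT_HIGH_AS_HIGH, L.HIGH),
        (C.HIGH, G.LOW_INT_AS_LOW, L.HIGH),
        (C.HIGH, G.INT_HIGH_AS_HIGH, L.HIGH),
    ])
    def test_merge_rules(self, cat, strategy, expected):
        assert cr.dichotomize(cat, strategy) is expected

    def test_predicted_outcome_is_a_bijection(self):
        preds = {lab: cr.predicted_outcome(lab) for lab in L}
        assert preds == {L.LOWISH: True, L.HIGH: False}


class TestAccuracy:
    @pytest.mark.parametrize("cells, expected", [
        # (high&noMMR, high&MMR, low&noMMR, low&MMR) -> accuracy percent
        ((11, 14, 22, 48), 62.11),
        ((4, 2, 29, 60), 67.37),
        ((23, 39, 10, 23), 48.42),
        ((20, 26, 13, 36), 58.95),
        ((4, 6, 29, 56), 63.16),
        ((7, 10, 26, 52), 62.11),
        ((19, 23, 14, 39), 61.05),
        ((5, 0, 0, 7), 100.00),
    ])
    def test_accuracy_values(self, cells, expected):
        assert cr.accuracy(cr.ContingencyTable(*cells)) == expected

    def test_rounding_is_half_up(self):
        # 1/800 = 0.125% rounds up to 0.13, not banker's 0.12.
        assert cr.accuracy(cr.ContingencyTable(1, 0, 799, 0)) == 0.13

    def test_empty_table_is_undefined(self):
        with pytest.raises(cr.UndefinedAccuracyError):
            cr.accuracy(cr.ContingencyTable(0, 0, 0, 0))

    def test_negative_cell_rejected(self):
        with pytest.raises(cr.ValidationError):
            cr.ContingencyTable(-1, 0, 0, 1)


class TestEnumeration:
    @pytest.mark.parametrize("n_systems, levels, count", [
        (4, 2, 16), (1, 2, 2), (2, 3, 9),
    ])
    def test_pattern_counts(self, n_systems, levels, count):
        assert len(cr.enumerate_combinations(n_systems, levels)) == count

    def test_deterministic_order(self):
        pats = cr.label_patterns()
        assert pats[0] == (L.LOWISH,) * 4
        assert pats[-1] == (L.HIGH,) * 4
        assert len(set(pats)) == 16

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            cr.enumerate_combinations(0, 2)


class TestContingencyBuilding:
    def test_toy_cohort_hand_counted(self):
        scored = make_scored_frame(
            [("HIGH", "LOW", "LOW", "LOW"),
             ("LOW", "LOW", "LOW", "LOW"),
             ("INTERMEDIATE", "HIGH", "HIGH", "HIGH")],
            mmr=[0, 1, 1])
        t = cr.build_contingency(scored, S.SOKAL, G.LOW_INT_AS_LOW)
        assert (t.n_high_no_mmr, t.n_high_mmr,
                t.n_low_no_mmr, t.n_low_mmr) == (1, 0, 0, 2)
        t2 = cr.build_contingency(scored, S.SOKAL, G.INT_HIGH_AS_HIGH)
        assert (t2.n_high_no_mmr, t2.n_high_mmr,
                t2.n_low_no_mmr, t2.n_low_mmr) == (1, 1, 0, 1)

    def test_missing_mmr_flag_instructs_exclusion(self):
        scored = make_scored_frame([("LOW",) * 4], mmr=[1])
        scored.loc[0, "mmr_achieved"] = np.nan
        with pytest.raises(cr.ValidationError, match="exclude"):
            cr.build_contingency(scored, S.SOKAL, G.LOW_INT_AS_LOW)

    def test_cells_sum_to_cohort_size(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            scored = random_scored_frame(rng)
            t = cr.build_contingency(scored, S.ELTS, G.LOW_INT_AS_LOW)
            assert t.total == len(scored)


def _patient_level_accuracy(scored, system, strategy):
    """Independent oracle: per-patient iteration, no contingency table."""
    agree = 0
    for _, row in scored.iterrows():
        cat = cr.RiskCategory(row[f"{system.value.lower()}_cat"])
        pred = cr.predicted_outcome(cr.dichotomize(cat, strategy))
        agree += int(pred == bool(row["mmr_achieved"]))
    frac = Decimal(agree) * 100 / Decimal(len(scored))
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


class TestPartition:
    def test_consensus_and_conflict_membership(self):
        scored = make_scored_frame(
            [("LOW", "INTERMEDIATE", "LOW", "LOW"),   # all LOWISH: consensus
             ("HIGH", "LOW", "LOW", "LOW"),           # one HIGH: conflict
             ("HIGH", "HIGH", "HIGH", "HIGH")],       # all HIGH: consensus
            mmr=[1, 1, 0])
        part = cr.partition(scored, G.LOW_INT_AS_LOW)
        assert part.n_consensus == 2
        assert part.n_conflict == 1
        assert part.n_consensus + part.n_conflict == part.n_total

    def test_partition_conservation(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scored = random_scored_frame(rng)
            part = cr.partition(scored, G.LOW_INT_AS_LOW)
            assert sum(r.total for r in part.rows) == len(scored)
            assert len(part.rows) == 16
            assert len(part.consensus_rows) == 2

    def test_accuracy_equivalence_patient_level_vs_table(self):
        # Cross-check the aggregated path against brute-force iteration on
        # 100 random cohorts.
        rng = np.random.default_rng(42)
        for i in range(100):
            scored = random_scored_frame(rng, n=int(rng.integers(5, 40)))
            system = list(S)[i % 4]
            strategy = G.LOW_INT_AS_LOW if i % 2 else G.INT_HIGH_AS_HIGH
            table = cr.build_contingency(scored, system, strategy)
            assert cr.accuracy(table) == _patient_level_accuracy(
                scored, system, strategy)

    def test_subgroup_agreement_decomposition(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            scored = random_scored_frame(rng)
            part = cr.partition(scored, G.LOW_INT_AS_LOW)
            for system in S:
                whole = cr.subgroup_contingency(part, "all", system)
                parts = [cr.subgroup_contingency(part, sub, system)
                         for sub in ("consensus", "conflict")]
                assert whole.n_agreements == sum(p.n_agreements
                                                 for p in parts)

    def test_eutos_invariant_under_both_strategies(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            scored = random_scored_frame(rng)
            t1 = cr.build_contingency(scored, S.EUTOS, G.LOW_INT_AS_LOW)
            t2 = cr.build_contingency(scored, S.EUTOS, G.INT_HIGH_AS_HIGH)
            assert t1 == t2

    def test_empty_subgroup_accuracy_undefined(self):
        scored = make_scored_frame([("LOW",) * 4, ("LOW",) * 4], mmr=[1, 0])
        part = cr.partition(scored, G.LOW_INT_AS_LOW)
        with pytest.raises(cr.UndefinedAccuracyError):
            cr.subgroup_accuracy(part, "conflict", S.SOKAL)


class TestReport:
    def test_single_patient_report_conserves_totals(self):
        scored = cr.score_cohort(
            cr.generate_cohort(cr.CohortConfig(n_patients=1, seed=2)))
        report = cr.consistency_report(scored, G.LOW_INT_AS_LOW)
        assert report.n_patients == 1
        for tables in report.marginal.values():
            for t in tables.values():
                assert t.total == 1
        part = report.partitions[G.LOW_INT_AS_LOW]
        assert part.n_consensus + part.n_conflict == 1

    def test_strategy_dominance_on_reconstructed_cohort(
            self, reconstructed_report):
        # Merging intermediate with low is at least as accurate as merging
        # it with high, for every three-level score, on the reference cohort.
        rep = reconstructed_report
        for system in (S.SOKAL, S.HASFORD, S.ELTS):
            assert rep.marginal_accuracy(G.LOW_INT_AS_LOW, system) >= \
                rep.marginal_accuracy(G.INT_HIGH_AS_HIGH, system)
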