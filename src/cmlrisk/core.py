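"""Prognostic risk scores for chronic myeloid leukemia and their consistency.

Four baseline prognostic indices — Sokal, Hasford (Euro), EUTOS and ELTS —
stratify newly diagnosed CML patients into risk categories from six
diagnosis-time variables: age, palpable spleen size (cm below the costal
margin), platelet count (x10^9/L) and the peripheral blast, eosinophil and
basophil percentages.  Because the four scores were fitted on different
populations against different endpoints, they routinely disagree on the same
patient.  This module implements

* the four score equations and their published risk-category cut-offs
  (``sokal_score`` .. ``elts_score``, ``categorize``, ``profile``);
* a consistency analysis that collapses each three-level score to two levels
  (intermediate merged with low, or with high), tabulates each system's
  dichotomized label against major molecular response (MMR, BCR-ABL1
  transcript <= 0.1%), enumerates the 2^4 joint label patterns, splits the
  cohort into a consensus group (all four labels agree) and a conflict group,
  and reports per-system accuracy in each subgroup (``partition``,
  ``consistency_report``);
* synthetic cohorts: a parametric generator whose marginals emulate a
  published 95-patient cohort and whose MMR outcome follows a logistic model
  on a standardized composite of the four scores (``generate_cohort``), and a
  constraint-driven reconstructor that builds a patient-level cohort whose
  aggregate tables reproduce a given set of published counts exactly
  (``reconstruct_cohort``);
* CSV input/output with validation, report rendering (markdown / JSON) and a
  command-line interface (``score``, ``analyze``, ``simulate``,
  ``reconstruct``).

The accuracy convention throughout: a HIGH dichotomized label predicts
failure to achieve MMR, a merged low/intermediate label predicts achievement;
accuracy is the percentage of patients whose label agrees with their observed
outcome.
"""

from __future__ import annotations

import enum
import itertools
import json
import logging
import math
import sys
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import click
import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

__version__ = "1.0.0"

logger = logging.getLogger("cmlrisk")

# ---------------------------------------------------------------------------
# Constants: score coefficients, category cut-offs, CSV schema
# ---------------------------------------------------------------------------

#: Cohort CSV column order (header row, UTF-8, '.' decimal separator).
COHORT_COLUMNS = [
    "patient_id",
    "age_years",
    "spleen_cm_bcm",
    "platelets_10e9_L",
    "blasts_pct",
    "eosinophils_pct",
    "basophils_pct",
    "mmr_achieved",
]

#: Columns appended by :func:`score_cohort`.
SCORED_COLUMNS = [
    "sokal_value", "sokal_cat",
    "hasford_value", "hasford_cat",
    "eutos_value", "eutos_cat",
    "elts_value", "elts_cat",
]

PERCENT_FIELDS = ("blasts_pct", "eosinophils_pct", "basophils_pct")

# Sokal 1984: hazard-ratio style score, exponential of a linear predictor
# centered at the derivation cohort means.
SOKAL_AGE_COEF = 0.0116
SOKAL_AGE_CENTER = 43.4
SOKAL_SPLEEN_COEF = 0.0345
SOKAL_SPLEEN_CENTER = 7.51
SOKAL_PLT_COEF = 0.188
SOKAL_PLT_CENTER = 0.563          # centered (platelets/700)^2
SOKAL_BLAST_COEF = 0.0887
SOKAL_BLAST_CENTER = 2.10

# Hasford 1998 (Euro score): linear predictor x 1000 with three indicator
# terms (age >= 50 y, basophils >= 3%, platelets >= 1500 x10^9/L).
HASFORD_AGE_COEF = 0.6666
HASFORD_SPLEEN_COEF = 0.0420
HASFORD_BLAST_COEF = 0.0584
HASFORD_EOS_COEF = 0.0413
HASFORD_BASO_COEF = 0.2039
HASFORD_PLT_COEF = 1.0956
HASFORD_SCALE = 1000.0

# EUTOS 2011: two-term linear score.
EUTOS_BASO_COEF = 7.0
EUTOS_SPLEEN_COEF = 4.0

# ELTS 2016: age enters as (completed years / 10)^3, platelets as an inverse
# square root, so the score diverges as platelets -> 0.
ELTS_AGE_COEF = 0.0025
ELTS_SPLEEN_COEF = 0.0615
ELTS_BLAST_COEF = 0.1052
ELTS_PLT_COEF = 0.4104


class ScoringSystem(str, enum.Enum):
    """The four prognostic scoring systems, in canonical report order."""

    SOKAL = "SOKAL"
    HASFORD = "HASFORD"
    EUTOS = "EUTOS"
    ELTS = "ELTS"


SYSTEMS: tuple[ScoringSystem, ...] = (
    ScoringSystem.SOKAL,
    ScoringSystem.HASFORD,
    ScoringSystem.EUTOS,
    ScoringSystem.ELTS,
)

#: Systems with a three-level category scale (EUTOS is already dichotomous).
THREE_LEVEL_SYSTEMS: tuple[ScoringSystem, ...] = (
    ScoringSystem.SOKAL,
    ScoringSystem.HASFORD,
    ScoringSystem.ELTS,
)


class RiskCategory(str, enum.Enum):
    LOW = "LOW"
    INTERMEDIATE = "INTERMEDIATE"
    HIGH = "HIGH"


# Published category boundaries.  Sokal: low < 0.8, intermediate 0.8-1.2,
# high > 1.2.  Hasford: low <= 780, intermediate 781-1480, high >= 1481; the
# score is continuous, so the gaps (780, 781) and (1480, 1481) are closed by
# extending the lower band upward: low <= 780 < intermediate <= 1480 < high.
# EUTOS: low < 87 <= high.  ELTS: low <= 1.5680 < intermediate <= 2.2185 <
# high (1.5680 is printed in both the low and intermediate ranges; the "<="
# wording of the low band wins).
CATEGORY_BOUNDS: dict[ScoringSystem, tuple[float, float] | tuple[float]] = {
    ScoringSystem.SOKAL: (0.8, 1.2),
    ScoringSystem.HASFORD: (780.0, 1480.0),
    ScoringSystem.EUTOS: (87.0,),
    ScoringSystem.ELTS: (1.5680, 2.2185),
}

# Whether the low band is closed at its upper boundary (value == bound is
# still LOW).  Sokal's intermediate band is closed at 0.8 ("0.8-1.2"), so the
# boundary value belongs to INTERMEDIATE; EUTOS 87 belongs to HIGH.
_LOW_CLOSED = {
    ScoringSystem.SOKAL: False,
    ScoringSystem.HASFORD: True,
    ScoringSystem.EUTOS: False,
    ScoringSystem.ELTS: True,
}


class GroupingStrategy(enum.IntEnum):
    """How a three-level category collapses to two levels.

    ``LOW_INT_AS_LOW`` (strategy 1) merges intermediate with low;
    ``INT_HIGH_AS_HIGH`` (strategy 2) merges intermediate with high.
    EUTOS, already dichotomous, is unaffected by either.
    """

    LOW_INT_AS_LOW = 1
    INT_HIGH_AS_HIGH = 2


class DichotomousLabel(str, enum.Enum):
    LOWISH = "LOWISH"   # low, or intermediate merged into low
    HIGH = "HIGH"


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class CmlRiskError(Exception):
    """Base class for package errors."""


class ValidationError(CmlRiskError, ValueError):
    """A record violates the input contract; names the offending field."""


class SchemaError(CmlRiskError, ValueError):
    """A cohort file's structure (header, types, ids) is invalid."""


class UndefinedAccuracyError(CmlRiskError, ZeroDivisionError):
    """Accuracy requested on an empty table or subgroup."""


class InfeasiblePatternError(CmlRiskError, RuntimeError):
    """Reconstruction could not find a patient for a category pattern."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientBaseline:
    """Diagnosis-time variables feeding all four score equations.

    ``age`` is in completed years (the ELTS age term floors it), ``spleen``
    in cm below the costal margin (0 = not palpable), ``platelets`` in
    x10^9/L (strictly positive: ELTS raises platelets to the -0.5 power),
    and the three differentials in percent of peripheral white cells.
    """

    patient_id: str
    age: float
    spleen: float
    platelets: float
    blasts: float
    eosinophils: float
    basophils: float

    def validate(self, strict: bool = True) -> None:
        """Check the field contract; raise :class:`ValidationError`.

        In lenient mode out-of-range percentages and ages are logged as
        warnings instead of raised; non-finite values and non-positive
        platelet counts are always errors.
        """
        for name in ("age", "spleen", "platelets", "blasts",
                     "eosinophils", "basophils"):
            v = getattr(self, name)
            if not isinstance(v, (int, float, np.integer, np.floating)):
                raise ValidationError(
                    f"patient {self.patient_id!r}: field {name!r} is not numeric")
            if not math.isfinite(float(v)):
                raise ValidationError(
                    f"patient {self.patient_id!r}: field {name!r} is not finite")
        if self.platelets <= 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: field 'platelets' must be > 0 "
                "(the ELTS platelet term diverges at 0)")
        soft: list[str] = []
        if self.age < 0:
            soft.append("age")
        if self.spleen < 0:
            soft.append("spleen")
        for name, attr in (("blasts", self.blasts),
                           ("eosinophils", self.eosinophils),
                           ("basophils", self.basophils)):
            if not 0.0 <= attr <= 100.0:
                soft.append(name)
        if soft:
            msg = (f"patient {self.patient_id!r}: field(s) {', '.join(soft)} "
                   "out of range")
            if strict:
                raise ValidationError(msg)
            logger.warning("%s (lenient mode: keeping record)", msg)


@dataclass(frozen=True)
class ScoreValue:
    """One system's continuous score plus its deterministic category."""

    system: ScoringSystem
    value: float
    category: RiskCategory


@dataclass(frozen=True)
class RiskProfile:
    """All four scores for one patient, keyed by system."""

    patient_id: str
    scores: Mapping[ScoringSystem, ScoreValue]

    def __post_init__(self) -> None:
        if set(self.scores) != set(SYSTEMS):
            missing = [s.value for s in SYSTEMS if s not in self.scores]
            raise ValidationError(
                f"patient {self.patient_id!r}: incomplete profile, "
                f"missing {missing}")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of dichotomized risk label against MMR outcome."""

    n_high_no_mmr: int
    n_high_mmr: int
    n_low_no_mmr: int
    n_low_mmr: int

    def __post_init__(self) -> None:
        for name in ("n_high_no_mmr", "n_high_mmr",
                     "n_low_no_mmr", "n_low_mmr"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"cell {name!r} must be a count, got {v}")

    @property
    def total(self) -> int:
        return (self.n_high_no_mmr + self.n_high_mmr
                + self.n_low_no_mmr + self.n_low_mmr)

    @property
    def n_agreements(self) -> int:
        """Patients whose label predicts their outcome (high<->no MMR)."""
        return self.n_high_no_mmr + self.n_low_mmr

    def to_dict(self) -> dict[str, int]:
        return {
            "n_high_no_mmr": self.n_high_no_mmr,
            "n_high_mmr": self.n_high_mmr,
            "n_low_no_mmr": self.n_low_no_mmr,
            "n_low_mmr": self.n_low_mmr,
        }


@dataclass(frozen=True)
class CombinationRow:
    """One joint label pattern (Sokal, Hasford, EUTOS, ELTS) with its counts."""

    pattern: tuple[DichotomousLabel, ...]
    n_mmr: int
    n_no_mmr: int

    @property
    def is_consensus(self) -> bool:
        return len(set(self.pattern)) == 1

    @property
    def total(self) -> int:
        return self.n_mmr + self.n_no_mmr

    def to_dict(self) -> dict:
        return {"pattern": [lab.value for lab in self.pattern],
                "n_mmr": self.n_mmr, "n_no_mmr": self.n_no_mmr}


@dataclass
class ConsistencyPartition:
    """Cohort split into consensus (all labels agree) and conflict groups.

    ``labels`` is the per-patient working frame: one dichotomized label
    column per system, the MMR flag, and a ``consensus`` indicator.  ``rows``
    holds all 2^4 combination rows in enumeration order.
    """

    strategy: GroupingStrategy
    rows: list[CombinationRow]
    labels: pd.DataFrame = field(repr=False)

    @property
    def n_consensus(self) -> int:
        return sum(r.total for r in self.rows if r.is_consensus)

    @property
    def n_conflict(self) -> int:
        return sum(r.total for r in self.rows if not r.is_consensus)

    @property
    def n_total(self) -> int:
        return len(self.labels)

    @property
    def consensus_rows(self) -> list[CombinationRow]:
        return [r for r in self.rows if r.is_consensus]

    @property
    def conflict_rows(self) -> list[CombinationRow]:
        return [r for r in self.rows if not r.is_consensus]


# ---------------------------------------------------------------------------
# Score engine
# ---------------------------------------------------------------------------
# Each score has a vectorized kernel over numpy arrays (shared by the cohort
# path and the reconstruction search) and a scalar wrapper that validates a
# PatientBaseline.

def _sokal_kernel(age, spleen, platelets, blasts):
    lin = (SOKAL_AGE_COEF * (np.asarray(age, float) - SOKAL_AGE_CENTER)
           + SOKAL_SPLEEN_COEF * (np.asarray(spleen, float) - SOKAL_SPLEEN_CENTER)
           + SOKAL_PLT_COEF * ((np.asarray(platelets, float) / 700.0) ** 2
                               - SOKAL_PLT_CENTER)
           + SOKAL_BLAST_COEF * (np.asarray(blasts, float) - SOKAL_BLAST_CENTER))
    return np.exp(lin)


def _hasford_kernel(age, spleen, platelets, blasts, eosinophils, basophils):
    return HASFORD_SCALE * (
        HASFORD_AGE_COEF * (np.asarray(age, float) >= 50.0)
        + HASFORD_SPLEEN_COEF * np.asarray(spleen, float)
        + HASFORD_BLAST_COEF * np.asarray(blasts, float)
        + HASFORD_EOS_COEF * np.asarray(eosinophils, float)
        + HASFORD_BASO_COEF * (np.asarray(basophils, float) >= 3.0)
        + HASFORD_PLT_COEF * (np.asarray(platelets, float) >= 1500.0))


def _eutos_kernel(spleen, basophils):
    return (EUTOS_BASO_COEF * np.asarray(basophils, float)
            + EUTOS_SPLEEN_COEF * np.asarray(spleen, float))


def _elts_kernel(age, spleen, platelets, blasts):
    # Age in completed years: floor a real-valued age before cubing.
    completed = np.floor(np.asarray(age, float))
    return (ELTS_AGE_COEF * (completed / 10.0) ** 3
            + ELTS_SPLEEN_COEF * np.asarray(spleen, float)
            + ELTS_BLAST_COEF * np.asarray(blasts, float)
            + ELTS_PLT_COEF * (np.asarray(platelets, float) / 1000.0) ** -0.5)


def sokal_score(p: PatientBaseline, strict: bool = True) -> float:
    """Sokal score: exp of the centered linear predictor; > 0."""
    p.validate(strict=strict)
    return float(_sokal_kernel(p.age, p.spleen, p.platelets, p.blasts))


def hasford_score(p: PatientBaseline, strict: bool = True) -> float:
    """Hasford (Euro) score: the six-term linear predictor scaled by 1000."""
    p.validate(strict=strict)
    return float(_hasford_kernel(p.age, p.spleen, p.platelets,
                                 p.blasts, p.eosinophils, p.basophils))


def eutos_score(p: PatientBaseline, strict: bool = True) -> float:
    """EUTOS score: 7 x basophils(%) + 4 x spleen(cm)."""
    p.validate(strict=strict)
    return float(_eutos_kernel(p.spleen, p.basophils))


def elts_score(p: PatientBaseline, strict: bool = True) -> float:
    """ELTS score; age enters as completed years, platelets as power -0.5."""
    p.validate(strict=strict)
    return float(_elts_kernel(p.age, p.spleen, p.platelets, p.blasts))


_SCORE_FUNCS = {
    ScoringSystem.SOKAL: sokal_score,
    ScoringSystem.HASFORD: hasford_score,
    ScoringSystem.EUTOS: eutos_score,
    ScoringSystem.ELTS: elts_score,
}


def categorize(system: ScoringSystem | str, value: float) -> RiskCategory:
    """Map a continuous score value to its system's risk category."""
    system = ScoringSystem(system)
    if not math.isfinite(value):
        raise ValidationError(f"{system.value} score value is not finite")
    bounds = CATEGORY_BOUNDS[system]
    if len(bounds) == 1:            # EUTOS: two categories only
        return RiskCategory.LOW if value < bounds[0] else RiskCategory.HIGH
    lo, hi = bounds
    low = value <= lo if _LOW_CLOSED[system] else value < lo
    if low:
        return RiskCategory.LOW
    return RiskCategory.INTERMEDIATE if value <= hi else RiskCategory.HIGH


def _categorize_kernel(system: ScoringSystem, values: np.ndarray) -> np.ndarray:
    """Vectorized categorize; returns codes 0=LOW, 1=INTERMEDIATE, 2=HIGH."""
    values = np.asarray(values, float)
    bounds = CATEGORY_BOUNDS[system]
    if len(bounds) == 1:
        return np.where(values < bounds[0], 0, 2)
    lo, hi = bounds
    low = values <= lo if _LOW_CLOSED[system] else values < lo
    return np.select([low, values <= hi], [0, 1], default=2)


_CAT_FROM_CODE = {0: RiskCategory.LOW, 1: RiskCategory.INTERMEDIATE,
                  2: RiskCategory.HIGH}
_CODE_FROM_CAT = {v: k for k, v in _CAT_FROM_CODE.items()}


def profile(p: PatientBaseline, strict: bool = True) -> RiskProfile:
    """Score one patient under all four systems."""
    scores = {}
    for system in SYSTEMS:
        value = _SCORE_FUNCS[system](p, strict=strict)
        scores[system] = ScoreValue(system, value, categorize(system, value))
    return RiskProfile(p.patient_id, scores)


def score_cohort(cohort: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Append the four score values and categories to a cohort frame.

    The input must carry the cohort CSV schema columns; the result appends
    ``<system>_value`` / ``<system>_cat`` pairs in canonical order.
    """
    _validate_cohort_frame(cohort, strict=strict)
    out = cohort.copy()
    age = out["age_years"].to_numpy(float)
    spleen = out["spleen_cm_bcm"].to_numpy(float)
    plt = out["platelets_10e9_L"].to_numpy(float)
    blasts = out["blasts_pct"].to_numpy(float)
    eos = out["eosinophils_pct"].to_numpy(float)
    baso = out["basophils_pct"].to_numpy(float)
    values = {
        ScoringSystem.SOKAL: _sokal_kernel(age, spleen, plt, blasts),
        ScoringSystem.HASFORD: _hasford_kernel(age, spleen, plt, blasts,
                                               eos, baso),
        ScoringSystem.EUTOS: _eutos_kernel(spleen, baso),
        ScoringSystem.ELTS: _elts_kernel(age, spleen, plt, blasts),
    }
    for system in SYSTEMS:
        name = system.value.lower()
        codes = _categorize_kernel(system, values[system])
        out[f"{name}_value"] = values[system]
        out[f"{name}_cat"] = [_CAT_FROM_CODE[c].value for c in codes]
    return out


def _validate_cohort_frame(cohort: pd.DataFrame, strict: bool = True) -> None:
    missing = [c for c in COHORT_COLUMNS[:-1] if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort frame missing column(s) {missing}")
    for _, row in cohort.iterrows():
        PatientBaseline(
            patient_id=str(row["patient_id"]),
            age=row["age_years"], spleen=row["spleen_cm_bcm"],
            platelets=row["platelets_10e9_L"], blasts=row["blasts_pct"],
            eosinophils=row["eosinophils_pct"], basophils=row["basophils_pct"],
        ).validate(strict=strict)


# ---------------------------------------------------------------------------
# Consistency analysis
# ---------------------------------------------------------------------------

def dichotomize(category: RiskCategory | str,
                strategy: GroupingStrategy) -> DichotomousLabel:
    """Collapse a three-level category to two levels under a merge strategy."""
    category = RiskCategory(category)
    strategy = GroupingStrategy(strategy)
    if category is RiskCategory.HIGH:
        return DichotomousLabel.HIGH
    if category is RiskCategory.LOW:
        return DichotomousLabel.LOWISH
    return (DichotomousLabel.LOWISH
            if strategy is GroupingStrategy.LOW_INT_AS_LOW
            else DichotomousLabel.HIGH)


def predicted_outcome(label: DichotomousLabel | str) -> bool:
    """Predicted MMR achievement: LOWISH predicts True, HIGH predicts False."""
    return DichotomousLabel(label) is DichotomousLabel.LOWISH


def _label_frame(scored: pd.DataFrame,
                 strategy: GroupingStrategy) -> pd.DataFrame:
    """Per-patient dichotomized labels (True = HIGH) plus the MMR flag."""
    for col in [f"{s.value.lower()}_cat" for s in SYSTEMS] + ["mmr_achieved"]:
        if col not in scored.columns:
            raise SchemaError(f"scored cohort missing column {col!r}")
    if scored["mmr_achieved"].isna().any():
        bad = scored.loc[scored["mmr_achieved"].isna(), "patient_id"].tolist()
        raise ValidationError(
            f"missing MMR flag for patient(s) {bad}; exclude incomplete "
            "records (read_cohort does this) before analysis")
    out = pd.DataFrame(index=scored.index)
    out["patient_id"] = scored["patient_id"].astype(str)
    for system in SYSTEMS:
        cats = scored[f"{system.value.lower()}_cat"]
        bad = ~cats.isin([c.value for c in RiskCategory])
        if bad.any():
            who = scored.loc[bad, "patient_id"].iloc[0]
            raise ValidationError(
                f"patient {who!r}: invalid {system.value} category")
        out[system.value] = [
            dichotomize(c, strategy) is DichotomousLabel.HIGH for c in cats]
    out["mmr_achieved"] = scored["mmr_achieved"].astype(int).astype(bool)
    return out


def build_contingency(scored: pd.DataFrame, system: ScoringSystem | str,
                      strategy: GroupingStrategy) -> ContingencyTable:
    """Tabulate one system's dichotomized label against the MMR outcome."""
    system = ScoringSystem(system)
    labels = _label_frame(scored, strategy)
    return _contingency_from_labels(labels[system.value].to_numpy(),
                                    labels["mmr_achieved"].to_numpy())


def _contingency_from_labels(high: np.ndarray,
                             mmr: np.ndarray) -> ContingencyTable:
    high = np.asarray(high, bool)
    mmr = np.asarray(mmr, bool)
    return ContingencyTable(
        n_high_no_mmr=int(np.sum(high & ~mmr)),
        n_high_mmr=int(np.sum(high & mmr)),
        n_low_no_mmr=int(np.sum(~high & ~mmr)),
        n_low_mmr=int(np.sum(~high & mmr)),
    )


def accuracy_exact(table: ContingencyTable) -> float:
    """Unrounded accuracy percent: 100 x agreements / total."""
    if table.total == 0:
        raise UndefinedAccuracyError("accuracy undefined on an empty table")
    return 100.0 * table.n_agreements / table.total


def accuracy(table: ContingencyTable) -> float:
    """Accuracy percent rounded half-up to two decimals."""
    if table.total == 0:
        raise UndefinedAccuracyError("accuracy undefined on an empty table")
    exact = Decimal(table.n_agreements) * 100 / Decimal(table.total)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def enumerate_combinations(n_systems: int,
                           labels_per_system: int) -> list[tuple[int, ...]]:
    """All joint label patterns, lexicographic with the first label smallest.

    Patterns are tuples of level codes ``0 .. labels_per_system - 1``, one
    entry per system in canonical system order; for dichotomized systems code
    0 is LOWISH and code 1 is HIGH, so the all-LOWISH pattern comes first and
    the all-HIGH pattern last.
    """
    if n_systems < 1 or labels_per_system < 1:
        raise ValueError("n_systems and labels_per_system must be >= 1")
    return list(itertools.product(range(labels_per_system), repeat=n_systems))


def label_patterns() -> list[tuple[DichotomousLabel, ...]]:
    """The 16 dichotomized patterns over (Sokal, Hasford, EUTOS, ELTS)."""
    order = (DichotomousLabel.LOWISH, DichotomousLabel.HIGH)
    return [tuple(order[i] for i in combo)
            for combo in enumerate_combinations(len(SYSTEMS), 2)]


def partition(scored: pd.DataFrame,
              strategy: GroupingStrategy = GroupingStrategy.LOW_INT_AS_LOW,
              ) -> ConsistencyPartition:
    """Split a scored cohort into consensus and conflict groups.

    A patient is in the consensus group when all four dichotomized labels
    agree; every other patient is in the conflict group.  The partition also
    carries the full 2^4 combination table split by MMR outcome.
    """
    strategy = GroupingStrategy(strategy)
    labels = _label_frame(scored, strategy)
    high = labels[[s.value for s in SYSTEMS]].to_numpy(bool)
    mmr = labels["mmr_achieved"].to_numpy(bool)
    labels = labels.assign(consensus=(high.all(axis=1) | (~high).all(axis=1)))
    rows = []
    for combo, pattern in zip(enumerate_combinations(len(SYSTEMS), 2),
                              label_patterns()):
        mask = (high == np.asarray(combo, bool)).all(axis=1)
        rows.append(CombinationRow(pattern=pattern,
                                   n_mmr=int(np.sum(mask & mmr)),
                                   n_no_mmr=int(np.sum(mask & ~mmr))))
    return ConsistencyPartition(strategy=strategy, rows=rows, labels=labels)


SUBGROUPS = ("all", "consensus", "conflict")


def _subgroup_mask(part: ConsistencyPartition, subgroup: str) -> np.ndarray:
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}; expected {SUBGROUPS}")
    cons = part.labels["consensus"].to_numpy(bool)
    if subgroup == "all":
        return np.ones(len(cons), bool)
    return cons if subgroup == "consensus" else ~cons


def subgroup_contingency(part: ConsistencyPartition, subgroup: str,
                         system: ScoringSystem | str) -> ContingencyTable:
    """One system's label-vs-MMR table restricted to a partition subgroup."""
    system = ScoringSystem(system)
    mask = _subgroup_mask(part, subgroup)
    return _contingency_from_labels(
        part.labels.loc[mask, system.value].to_numpy(),
        part.labels.loc[mask, "mmr_achieved"].to_numpy())


def subgroup_accuracy(part: ConsistencyPartition, subgroup: str,
                      system: ScoringSystem | str) -> float:
    """Accuracy of one system within all / consensus / conflict patients."""
    table = subgroup_contingency(part, subgroup, system)
    if table.total == 0:
        raise UndefinedAccuracyError(
            f"subgroup {subgroup!r} is empty; accuracy undefined")
    return accuracy(table)


@dataclass
class AccuracyReport:
    """Everything the consistency analysis computes for one cohort.

    ``marginal`` holds, under both merge strategies, each system's 2x2 table
    on all patients; ``partitions`` the consensus/conflict split (and 2^4
    combination table) for the requested strategy or strategies; and
    ``subgroup_accuracy`` each system's accuracy within all / consensus /
    conflict patients of each partition (``None`` for an empty subgroup).
    Consensus-group misclassification is reported against both denominators
    (the consensus group itself and the whole cohort).
    """

    n_patients: int
    marginal: dict[GroupingStrategy, dict[ScoringSystem, ContingencyTable]]
    partitions: dict[GroupingStrategy, ConsistencyPartition]
    schema_version: int = 1

    def marginal_accuracy(self, strategy: GroupingStrategy,
                          system: ScoringSystem) -> float:
        return accuracy(self.marginal[GroupingStrategy(strategy)]
                        [ScoringSystem(system)])

    def subgroup_accuracies(self, strategy: GroupingStrategy
                            ) -> dict[str, dict[ScoringSystem, float | None]]:
        part = self.partitions[GroupingStrategy(strategy)]
        out: dict[str, dict[ScoringSystem, float | None]] = {}
        for sub in SUBGROUPS:
            row: dict[ScoringSystem, float | None] = {}
            for system in SYSTEMS:
                try:
                    row[system] = subgroup_accuracy(part, sub, system)
                except UndefinedAccuracyError:
                    row[system] = None
            out[sub] = row
        return out

    def consensus_misclassification(self, strategy: GroupingStrategy) -> dict:
        part = self.partitions[GroupingStrategy(strategy)]
        n_wrong = sum(
            (r.n_no_mmr if r.pattern[0] is DichotomousLabel.LOWISH else r.n_mmr)
            for r in part.consensus_rows)
        return {
            "n_misclassified": n_wrong,
            "pct_of_consensus": (_round2(100 * n_wrong / part.n_consensus)
                                 if part.n_consensus else None),
            "pct_of_cohort": (_round2(100 * n_wrong / part.n_total)
                              if part.n_total else None),
        }

    def to_dict(self) -> dict:
        body: dict = {
            "schema_version": self.schema_version,
            "package_version": __version__,
            "n_patients": self.n_patients,
            "systems": [s.value for s in SYSTEMS],
            "marginal": {},
            "consistency": {},
        }
        for strategy, tables in self.marginal.items():
            body["marginal"][str(int(strategy))] = {
                system.value: {
                    "table": table.to_dict(),
                    "accuracy": accuracy(table) if table.total else None,
                    "accuracy_exact": (accuracy_exact(table)
                                       if table.total else None),
                } for system, table in tables.items()}
        for strategy, part in self.partitions.items():
            subacc = self.subgroup_accuracies(strategy)
            body["consistency"][str(int(strategy))] = {
                "n_consensus": part.n_consensus,
                "n_conflict": part.n_conflict,
                "combination_table": [r.to_dict() for r in part.rows],
                "subgroup_accuracy": {
                    sub: {system.value: subacc[sub][system]
                          for system in SYSTEMS}
                    for sub in SUBGROUPS},
                "consensus_misclassification":
                    self.consensus_misclassification(strategy),
            }
        return body


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


def consistency_report(scored: pd.DataFrame,
                       strategy: GroupingStrategy | str | int = "both",
                       ) -> AccuracyReport:
    """Run the full consistency analysis on a scored, MMR-complete cohort.

    ``strategy`` selects which merge rule drives the consensus/conflict
    partition (``"both"`` computes both); the per-system marginal tables are
    always reported under both rules.
    """
    if strategy == "both":
        part_strategies = [GroupingStrategy.LOW_INT_AS_LOW,
                           GroupingStrategy.INT_HIGH_AS_HIGH]
    else:
        part_strategies = [GroupingStrategy(int(strategy))]
    marginal = {
        strat: {system: build_contingency(scored, system, strat)
                for system in SYSTEMS}
        for strat in (GroupingStrategy.LOW_INT_AS_LOW,
                      GroupingStrategy.INT_HIGH_AS_HIGH)}
    partitions = {strat: partition(scored, strat) for strat in part_strategies}
    return AccuracyReport(n_patients=len(scored), marginal=marginal,
                          partitions=partitions)


# ---------------------------------------------------------------------------
# Synthetic cohorts: parametric generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """Marginal distribution of one baseline variable.

    ``median`` and ``sd`` parameterize the underlying (log-)normal; samples
    are truncated to ``[lo, hi]``.  The underlying location is solved so the
    *truncated* median hits the target.  ``family`` is ``"normal"`` or
    ``"lognormal"`` (right-skewed, for platelet counts).
    """

    median: float
    sd: float
    lo: float
    hi: float
    family: str = "normal"
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.median < self.hi:
            raise ValidationError(
                f"median {self.median} must lie inside ({self.lo}, {self.hi})")
        if self.family not in ("normal", "lognormal"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.family == "lognormal" and self.lo <= 0:
            raise ValidationError("lognormal variables need lo > 0")


def _default_variables() -> dict[str, VariableSpec]:
    # Reference cohort marginals: median, SD and observed range per variable.
    # The printed eosinophil range (0-0.07) is inconsistent with its median
    # (0.83); 0-7 is used, symmetric with the basophil range.
    return {
        "age_years": VariableSpec(40.21, 15.13, 18, 74, integer=True),
        "spleen_cm_bcm": VariableSpec(8.33, 7.53, 0, 25),
        "platelets_10e9_L": VariableSpec(510.97, 439.88, 4.42, 2876,
                                         family="lognormal"),
        "blasts_pct": VariableSpec(1.50, 1.39, 0, 10),
        "eosinophils_pct": VariableSpec(0.83, 1.24, 0, 7),
        "basophils_pct": VariableSpec(1.32, 1.10, 0, 7),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Configuration for :func:`generate_cohort`.

    ``association`` is the log-odds decrease in MMR per SD of the
    standardized four-score composite (0 = outcome independent of risk);
    ``baseline_mmr_rate`` is the marginal achievement probability (default:
    the 62/95 rate of the reference cohort).
    """

    n_patients: int
    seed: int = 0
    association: float = 1.0
    baseline_mmr_rate: float = 62 / 95
    variables: Mapping[str, VariableSpec] = field(
        default_factory=_default_variables)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not 0.0 < self.baseline_mmr_rate < 1.0:
            raise ValidationError("baseline_mmr_rate must be in (0, 1)")
        missing = set(_default_variables()) - set(self.variables)
        if missing:
            raise ValidationError(f"missing variable spec(s): {sorted(missing)}")


def _truncnorm_loc(median: float, sd: float, lo: float, hi: float) -> float:
    """Location such that the [lo, hi]-truncated normal has the target median."""

    def f(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.ppf(0.5, a, b, loc=loc, scale=sd) - median

    return optimize.brentq(f, lo - 8 * sd, hi + 8 * sd, xtol=1e-10)


def _lognormal_sigma(median: float, sd: float) -> float:
    # For an untruncated lognormal, (sd/median)^2 = t(t-1) with t = e^sigma^2.
    r = (sd / median) ** 2
    t = (1 + math.sqrt(1 + 4 * r)) / 2
    return math.sqrt(math.log(t))


def _sample_variable(spec: VariableSpec, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    if spec.family == "lognormal":
        sigma = _lognormal_sigma(spec.median, spec.sd)
        loc = _truncnorm_loc(math.log(spec.median), sigma,
                             math.log(spec.lo), math.log(spec.hi))
        a = (math.log(spec.lo) - loc) / sigma
        b = (math.log(spec.hi) - loc) / sigma
        draws = np.exp(stats.truncnorm.rvs(a, b, loc=loc, scale=sigma,
                                           size=n, random_state=rng))
    else:
        loc = _truncnorm_loc(spec.median, spec.sd, spec.lo, spec.hi)
        a, b = (spec.lo - loc) / spec.sd, (spec.hi - loc) / spec.sd
        draws = stats.truncnorm.rvs(a, b, loc=loc, scale=spec.sd,
                                    size=n, random_state=rng)
    return np.floor(draws) if spec.integer else draws


def risk_composite(scored: pd.DataFrame) -> np.ndarray:
    """Standardized composite of the four score values (mean of z-scores).

    Deterministic given the scored cohort; used both to simulate the MMR
    outcome and to re-estimate the outcome model from simulated data.
    """
    zs = []
    for system in SYSTEMS:
        v = scored[f"{system.value.lower()}_value"].to_numpy(float)
        sd = v.std()
        zs.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
    comp = np.mean(zs, axis=0)
    sd = comp.std()
    return (comp - comp.mean()) / sd if sd > 0 else comp


def generate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort with the configured marginals and outcome model.

    Baseline variables are independent truncated (log-)normals; the MMR flag
    is Bernoulli with logit = logit(baseline rate) - association x composite,
    where the composite is the standardized mean of the four score z-scores.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    data = {"patient_id": [f"S{i + 1:05d}" for i in range(cfg.n_patients)]}
    for name in COHORT_COLUMNS[1:-1]:
        data[name] = _sample_variable(cfg.variables[name], cfg.n_patients, rng)
    cohort = pd.DataFrame(data)
    scored = score_cohort(cohort)
    comp = risk_composite(scored)
    logit = special.logit(cfg.baseline_mmr_rate) - cfg.association * comp
    cohort["mmr_achieved"] = (rng.random(cfg.n_patients)
                              < special.expit(logit)).astype(int)
    return cohort


def fit_logistic_slope(x: np.ndarray, y: np.ndarray,
                       max_iter: int = 100, tol: float = 1e-10
                       ) -> tuple[float, float, float]:
    """Newton fit of logit P(y=1) = a + b x; returns (a, b, SE of b)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        p = special.expit(X @ beta)
        w = p * (1 - p)
        H = X.T @ (X * w[:, None])
        step = np.linalg.solve(H, X.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    p = special.expit(X @ beta)
    cov = np.linalg.inv(X.T @ (X * (p * (1 - p))[:, None]))
    return float(beta[0]), float(beta[1]), float(math.sqrt(cov[1, 1]))


# ---------------------------------------------------------------------------
# Synthetic cohorts: reconstruction from aggregate tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetTables:
    """Aggregate targets a reconstructed cohort must reproduce exactly.

    ``rows`` maps each of the 2^4 dichotomized patterns (intermediate merged
    with low) to its (MMR, no-MMR) counts.  ``merge_high_high`` gives, for
    each three-level system, the number of patients counted high-risk when
    intermediate is instead merged with high, split by MMR; the difference
    from the pattern-derived high counts fixes how many merged-low patients
    are intermediate rather than low.  EUTOS entries must match the
    pattern-derived counts (it has no intermediate category).
    """

    rows: Mapping[tuple[DichotomousLabel, ...], tuple[int, int]]
    merge_high_high: Mapping[ScoringSystem, tuple[int, int]]

    def __post_init__(self) -> None:
        expected = set(label_patterns())
        if set(self.rows) != expected:
            raise ValidationError(
                "targets must specify all 16 combination patterns")
        for pattern, (n_mmr, n_no) in self.rows.items():
            if n_mmr < 0 or n_no < 0:
                raise ValidationError(f"negative count for pattern {pattern}")
        for system in SYSTEMS:
            hi_mmr, hi_no = self.pattern_high_counts(system)
            m_mmr, m_no = self.merge_high_high[system]
            if system is ScoringSystem.EUTOS:
                if (m_mmr, m_no) != (hi_mmr, hi_no):
                    raise ValidationError(
                        "EUTOS merged-high counts must equal the "
                        "pattern-derived counts (no intermediate category)")
            elif m_mmr < hi_mmr or m_no < hi_no:
                raise ValidationError(
                    f"{system.value}: merged-high counts below the "
                    "pattern-derived high counts")

    @property
    def total(self) -> int:
        return sum(a + b for a, b in self.rows.values())

    def pattern_high_counts(self, system: ScoringSystem) -> tuple[int, int]:
        """(MMR, no-MMR) counts with this system's label HIGH, from rows."""
        idx = SYSTEMS.index(ScoringSystem(system))
        mmr = no = 0
        for pattern, (n_mmr, n_no) in self.rows.items():
            if pattern[idx] is DichotomousLabel.HIGH:
                mmr += n_mmr
                no += n_no
        return mmr, no

    def intermediate_need(self, system: ScoringSystem) -> tuple[int, int]:
        """(MMR, no-MMR) patients that must be INTERMEDIATE for this system."""
        hi = self.pattern_high_counts(system)
        merged = self.merge_high_high[ScoringSystem(system)]
        return merged[0] - hi[0], merged[1] - hi[1]

    @classmethod
    def from_dict(cls, payload: Mapping) -> "TargetTables":
        rows = {}
        for entry in payload["combination_rows"]:
            pattern = tuple(DichotomousLabel(p) for p in entry["pattern"])
            rows[pattern] = (int(entry["n_mmr"]), int(entry["n_no_mmr"]))
        merged = payload.get("merge_high_high_counts")
        if merged is None:
            # No alternative-merge information: treat every merged-low
            # patient as genuinely low-risk.
            obj = cls.__new__(cls)
            object.__setattr__(obj, "rows", rows)
            hh = {}
            for system in SYSTEMS:
                idx = SYSTEMS.index(system)
                mmr = sum(v[0] for p, v in rows.items()
                          if p[idx] is DichotomousLabel.HIGH)
                no = sum(v[1] for p, v in rows.items()
                         if p[idx] is DichotomousLabel.HIGH)
                hh[system] = (mmr, no)
            return cls(rows=rows, merge_high_high=hh)
        hh = {ScoringSystem(k): (int(v["n_mmr"]), int(v["n_no_mmr"]))
              for k, v in merged.items()}
        return cls(rows=rows, merge_high_high=hh)

    @classmethod
    def builtin(cls, name: str = "table4") -> "TargetTables":
        """The packaged published-cohort targets (95 patients)."""
        if name != "table4":
            raise ValueError(f"unknown builtin target set {name!r}")
        payload = json.loads(
            resources.files("cmlrisk").joinpath("builtin_targets.json")
            .read_text("utf-8"))
        return cls.from_dict(payload)


# Uniform search box for reconstruction, deliberately wider than the
# reference cohort's observed ranges so every clinically coherent category
# combination is reachable (very low platelet counts, for instance, are what
# make an ELTS-high / Sokal-low patient possible).
_SEARCH_BOX = {
    "age_years": (16, 85),          # integers
    "spleen_cm_bcm": (0.0, 30.0),
    "platelets_10e9_L": (4.42, 2876.0),
    "blasts_pct": (0.0, 15.0),
    "eosinophils_pct": (0.0, 10.0),
    "basophils_pct": (0.0, 10.0),
}

#: Canonical order of full category tuples (3 x 3 x 2 x 3); indexes the
#: per-pattern PRNG stream so each exemplar search is independent.
_CATEGORY_TUPLES: list[tuple[int, ...]] = [
    combo for combo in itertools.product(range(3), range(3), range(3), range(3))
    if combo[2] != 1]               # EUTOS has no intermediate


_VARIABLE_ORDER = ("age_years", "spleen_cm_bcm", "platelets_10e9_L",
                   "blasts_pct", "eosinophils_pct", "basophils_pct")

# Typical score magnitudes, used to put the four category-violation
# distances on a common footing in the refinement objective.
_SCORE_SCALE = {ScoringSystem.SOKAL: 1.0, ScoringSystem.HASFORD: 1000.0,
                ScoringSystem.EUTOS: 87.0, ScoringSystem.ELTS: 1.0}


def _category_codes(age, spleen, platelets, blasts, eos, baso) -> np.ndarray:
    """Stacked (n, 4) category codes; age is floored to completed years."""
    age = np.floor(np.asarray(age, float))
    return np.column_stack([
        _categorize_kernel(ScoringSystem.SOKAL,
                           _sokal_kernel(age, spleen, platelets, blasts)),
        _categorize_kernel(ScoringSystem.HASFORD,
                           _hasford_kernel(age, spleen, platelets, blasts,
                                           eos, baso)),
        _categorize_kernel(ScoringSystem.EUTOS, _eutos_kernel(spleen, baso)),
        _categorize_kernel(ScoringSystem.ELTS,
                           _elts_kernel(age, spleen, platelets, blasts)),
    ])


def _category_interval(system: ScoringSystem, code: int
                       ) -> tuple[float, float]:
    bounds = CATEGORY_BOUNDS[system]
    if len(bounds) == 1:
        return (-math.inf, bounds[0]) if code == 0 else (bounds[0], math.inf)
    lo, hi = bounds
    return {0: (-math.inf, lo), 1: (lo, hi), 2: (hi, math.inf)}[code]


def _find_patient(cat_codes: tuple[int, int, int, int], seed: int,
                  max_draws: int = 1_000_000, batch: int = 20_000,
                  de_restarts: int = 5,
                  de_maxiter: int = 400) -> dict[str, float]:
    """Search the clinical box for a patient with these exact categories.

    ``cat_codes`` are (Sokal, Hasford, EUTOS, ELTS) codes with 0=LOW,
    1=INTERMEDIATE, 2=HIGH.  Stage 1 is rejection sampling from uniform
    draws over the box; patterns whose feasible region is too thin for that
    (several scores pinned near their boundaries at once) fall through to a
    seeded differential-evolution search that minimizes the summed distance
    of each score from its target category interval.  The PRNG streams are
    derived from the target tuple's canonical index, so each pattern's
    exemplar is reproducible independently of the others.
    """
    idx = _CATEGORY_TUPLES.index(tuple(cat_codes))
    rng = np.random.default_rng([seed, idx])
    target = np.asarray(cat_codes)
    drawn = 0
    while drawn < max_draws:
        n = min(batch, max_draws - drawn)
        drawn += n
        lo, hi = _SEARCH_BOX["age_years"]
        cols = {"age_years": rng.integers(lo, hi + 1, n).astype(float)}
        for name in _VARIABLE_ORDER[1:]:
            lo, hi = _SEARCH_BOX[name]
            cols[name] = rng.uniform(lo, hi, n)
        codes = _category_codes(*(cols[k] for k in _VARIABLE_ORDER))
        hits = np.flatnonzero((codes == target).all(axis=1))
        if hits.size:
            i = int(hits[0])
            return {name: float(vals[i]) for name, vals in cols.items()}

    def violation(x: np.ndarray) -> float:
        age = math.floor(x[0])
        values = {
            ScoringSystem.SOKAL: float(_sokal_kernel(age, x[1], x[2], x[3])),
            ScoringSystem.HASFORD: float(_hasford_kernel(age, x[1], x[2],
                                                         x[3], x[4], x[5])),
            ScoringSystem.EUTOS: float(_eutos_kernel(x[1], x[5])),
            ScoringSystem.ELTS: float(_elts_kernel(age, x[1], x[2], x[3])),
        }
        total = 0.0
        for system, code in zip(SYSTEMS, cat_codes):
            if categorize(system, values[system]) is _CAT_FROM_CODE[code]:
                continue
            lo, hi = _category_interval(system, code)
            v = values[system]
            # Distance to the target interval plus a nudge toward its
            # interior, so open boundaries are crossed cleanly.
            total += (max(0.0, lo - v, v - hi) + 1e-9) / _SCORE_SCALE[system]
        return total

    bounds = [_SEARCH_BOX[name] for name in _VARIABLE_ORDER]
    for restart in range(de_restarts):
        result = optimize.differential_evolution(
            violation, bounds, seed=np.random.default_rng([seed, idx, restart]),
            maxiter=de_maxiter, popsize=40, tol=0, mutation=(0.3, 1.2),
            recombination=0.9, polish=False, init="sobol",
            callback=lambda xk, convergence=0: violation(xk) == 0.0)
        x = result.x
        cols = dict(zip(_VARIABLE_ORDER, x))
        cols["age_years"] = float(math.floor(cols["age_years"]))
        codes = _category_codes(*(np.asarray([cols[k]])
                                  for k in _VARIABLE_ORDER))[0]
        if (codes == target).all():
            return {k: float(v) for k, v in cols.items()}
    names = tuple(_CAT_FROM_CODE[c].value for c in cat_codes)
    raise InfeasiblePatternError(
        f"no patient found for category pattern {names} "
        f"within {max_draws} draws plus refinement")


def reconstruct_cohort(targets: TargetTables, seed: int = 0,
                       max_draws: int = 1_000_000) -> pd.DataFrame:
    """Build a patient-level cohort reproducing the aggregate targets exactly.

    For every combination pattern the stated number of patients is emitted
    with matching MMR flags (assigned deterministically, since the targets
    fix them).  Within each system's merged-low margin, the required number
    of intermediate-category patients (the excess of the alternative-merge
    high counts over the pattern-derived high counts) is allocated greedily
    over the pattern cells in enumeration order, separately per MMR stratum.
    Each distinct full-category tuple is realized by one exemplar found by
    rejection sampling; patients sharing a tuple share covariates.  Every
    emitted patient is re-scored and checked against its intended categories.
    """
    patterns = label_patterns()
    remaining = {
        mmr_flag: {system: targets.intermediate_need(system)[0 if mmr_flag else 1]
                   for system in THREE_LEVEL_SYSTEMS}
        for mmr_flag in (True, False)}
    # Per pattern cell and stratum: how many of the cell's patients carry the
    # intermediate category for each three-level system (cell-initial ones).
    plan: list[tuple[tuple[int, ...], bool, int, dict[ScoringSystem, int]]] = []
    for pattern in patterns:
        combo = tuple(0 if lab is DichotomousLabel.LOWISH else 2
                      for lab in pattern)
        n_mmr, n_no = targets.rows[pattern]
        for mmr_flag, count in ((True, n_mmr), (False, n_no)):
            if count == 0:
                continue
            k = {}
            for si, system in enumerate(SYSTEMS):
                if system not in THREE_LEVEL_SYSTEMS or combo[si] == 2:
                    continue
                take = min(remaining[mmr_flag][system], count)
                remaining[mmr_flag][system] -= take
                k[system] = take
            plan.append((combo, mmr_flag, count, k))
    for mmr_flag, by_system in remaining.items():
        for system, left in by_system.items():
            if left:
                raise ValidationError(
                    f"{system.value}: cannot place {left} intermediate "
                    f"patient(s) in the {'MMR' if mmr_flag else 'no-MMR'} "
                    "stratum; targets are inconsistent")

    exemplars: dict[tuple[int, ...], dict[str, float]] = {}
    records: list[dict] = []
    for combo, mmr_flag, count, k in plan:
        for j in range(count):
            cats = list(combo)
            for si, system in enumerate(SYSTEMS):
                if system in k and j < k[system]:
                    cats[si] = 1
            key = tuple(cats)
            if key not in exemplars:
                exemplars[key] = _find_patient(key, seed, max_draws=max_draws)
            rec = dict(exemplars[key])
            rec["mmr_achieved"] = int(mmr_flag)
            rec["_cats"] = key
            records.append(rec)
    cohort = pd.DataFrame.from_records(records)
    cohort.insert(0, "patient_id",
                  [f"R{i + 1:03d}" for i in range(len(cohort))])
    intended = cohort.pop("_cats")
    # Satisfiability is verified by scoring, never trusted from bookkeeping.
    scored = score_cohort(cohort)
    for si, system in enumerate(SYSTEMS):
        got = scored[f"{system.value.lower()}_cat"]
        want = [_CAT_FROM_CODE[c[si]].value for c in intended]
        if list(got) != want:
            raise InfeasiblePatternError(
                f"reconstructed cohort failed {system.value} category "
                "verification")
    return cohort[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# I/O: cohort CSV reading/writing with validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionLog:
    """Record of patients dropped for missing MMR before analysis."""

    n_read: int
    n_excluded: int
    excluded_ids: tuple[str, ...]

    @property
    def n_analyzable(self) -> int:
        return self.n_read - self.n_excluded


def read_cohort(path: str | Path,
                strict: bool = True) -> tuple[pd.DataFrame, ExclusionLog]:
    """Read and validate a cohort CSV; drop records with a missing MMR flag.

    Returns the analyzable records and an exclusion log.  Strict mode raises
    on out-of-range values; lenient mode logs warnings and keeps them.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype={"patient_id": str},
                          float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty, expected header "
                          f"{COHORT_COLUMNS}") from None
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: malformed header, missing {missing}")
    dup = raw["patient_id"][raw["patient_id"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"{path}: duplicate patient_id {dup.iloc[0]!r}")
    for col in COHORT_COLUMNS[1:]:
        try:
            raw[col] = pd.to_numeric(raw[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {col!r} is not numeric: {exc}"
                              ) from None
        if col != "mmr_achieved" and raw[col].isna().any():
            who = raw.loc[raw[col].isna(), "patient_id"].iloc[0]
            raise SchemaError(
                f"{path}: missing value in {col!r} for patient {who!r}")
    bad_flag = ~raw["mmr_achieved"].isin([0, 1]) & raw["mmr_achieved"].notna()
    if bad_flag.any():
        who = raw.loc[bad_flag, "patient_id"].iloc[0]
        raise SchemaError(f"{path}: mmr_achieved must be 0, 1 or empty "
                          f"(patient {who!r})")
    excluded = raw["mmr_achieved"].isna()
    log = ExclusionLog(
        n_read=len(raw),
        n_excluded=int(excluded.sum()),
        excluded_ids=tuple(raw.loc[excluded, "patient_id"]))
    if log.n_excluded:
        logger.info("excluded %d of %d record(s) with missing MMR flag: %s",
                    log.n_excluded, log.n_read, ", ".join(log.excluded_ids))
    cohort = raw.loc[~excluded].reset_index(drop=True)
    cohort["mmr_achieved"] = cohort["mmr_achieved"].astype(int)
    _validate_cohort_frame(cohort, strict=strict)
    return cohort, log


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort (optionally scored) CSV; floats keep full precision."""
    cols = [c for c in COHORT_COLUMNS + SCORED_COLUMNS if c in cohort.columns]
    # %.17g guarantees the binary float survives the text round trip.
    cohort[cols].to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _md_table(headers: Sequence[str], rows: Iterable[Sequence]) -> str:
    lines = ["| " + " | ".join(str(h) for h in headers) + " |",
             "|" + "|".join(" --- " for _ in headers) + "|"]
    for row in rows:
        lines.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(lines)


def _fmt_acc(value: float | None) -> str:
    return "n/a" if value is None else f"{value:.2f}"


_STRATEGY_TITLE = {
    GroupingStrategy.LOW_INT_AS_LOW: "intermediate merged with low",
    GroupingStrategy.INT_HIGH_AS_HIGH: "intermediate merged with high",
}

_HIGH_ROW_NAME = {
    GroupingStrategy.LOW_INT_AS_LOW: "High",
    GroupingStrategy.INT_HIGH_AS_HIGH: "Intermediate and high",
}
_LOW_ROW_NAME = {
    GroupingStrategy.LOW_INT_AS_LOW: "Low and intermediate",
    GroupingStrategy.INT_HIGH_AS_HIGH: "Low",
}


def _pattern_cell(system: ScoringSystem, label: DichotomousLabel) -> str:
    if label is DichotomousLabel.HIGH:
        return "High"
    return "Low" if system is ScoringSystem.EUTOS else "Low and intermediate"


def render_report(report: AccuracyReport, fmt: str = "md") -> str:
    """Render an :class:`AccuracyReport` as markdown or JSON."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if fmt != "md":
        raise ValueError(f"unknown report format {fmt!r}")
    out = [f"# CML risk-score consistency report",
           "",
           f"Patients analyzed: {report.n_patients}", ""]
    out.append("## Risk groups versus MMR, per merge strategy")
    for strategy, tables in report.marginal.items():
        out.append("")
        out.append(f"### Strategy {int(strategy)}: "
                   f"{_STRATEGY_TITLE[strategy]}")
        rows = []
        for system, t in tables.items():
            eutos = system is ScoringSystem.EUTOS
            hi_name = "High" if eutos else _HIGH_ROW_NAME[strategy]
            lo_name = "Low" if eutos else _LOW_ROW_NAME[strategy]
            acc = _fmt_acc(accuracy(t) if t.total else None)
            rows.append([system.value.title(), hi_name,
                         t.n_high_no_mmr + t.n_high_mmr,
                         t.n_high_no_mmr, t.n_high_mmr, acc])
            rows.append(["", lo_name, t.n_low_no_mmr + t.n_low_mmr,
                         t.n_low_no_mmr, t.n_low_mmr, ""])
        out.append("")
        out.append(_md_table(
            ["Score", "Risk group", "n", "Not achieving MMR",
             "Achieving MMR", "Accuracy"], rows))
    for strategy, part in report.partitions.items():
        out.append("")
        out.append(f"## Consistency analysis (strategy {int(strategy)}: "
                   f"{_STRATEGY_TITLE[strategy]})")
        out.append("")
        out.append(f"Consensus group: {part.n_consensus} patient(s); "
                   f"conflict group: {part.n_conflict} patient(s).")
        rows = []
        # Conflict rows first, then consensus, mirroring the published layout.
        for r in part.conflict_rows + part.consensus_rows:
            rows.append(["conflict" if not r.is_consensus else "consensus",
                         *(_pattern_cell(s, lab)
                           for s, lab in zip(SYSTEMS, r.pattern)),
                         r.n_mmr, r.n_no_mmr])
        out.append("")
        out.append(_md_table(
            ["Group", "Sokal", "Hasford", "EUTOS", "ELTS",
             "Achieving MMR", "Not achieving MMR"], rows))
        subacc = report.subgroup_accuracies(strategy)
        out.append("")
        out.append("### Per-score accuracy by subgroup")
        out.append("")
        out.append(_md_table(
            ["Subgroup"] + [s.value.title() for s in SYSTEMS],
            [[sub] + [_fmt_acc(subacc[sub][s]) for s in SYSTEMS]
             for sub in SUBGROUPS]))
        mis = report.consensus_misclassification(strategy)
        out.append("")
        out.append(
            f"Consensus-group misclassification: {mis['n_misclassified']} "
            f"patient(s) ({_fmt_acc(mis['pct_of_consensus'])}% of the "
            f"consensus group; {_fmt_acc(mis['pct_of_cohort'])}% of the "
            "cohort).")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Command-line interface
# ---------------------------------------------------------------------------

EXIT_VALIDATION = 2
EXIT_INFEASIBLE = 3


def _configure_logging(level: str) -> None:
    logging.basicConfig(level=getattr(logging, level.upper()),
                        format="%(levelname)s %(name)s: %(message)s")


@click.group()
@click.option("--seed", type=int, default=0, show_default=True,
              help="Seed for all randomness.")
@click.option("--log-level", default="INFO", show_default=True,
              type=click.Choice(["DEBUG", "INFO", "WARNING", "ERROR"],
                                case_sensitive=False))
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="YAML file with per-command option defaults.")
@click.version_option(__version__)
@click.pass_context
def cli(ctx: click.Context, seed: int, log_level: str,
        config_path: str | None) -> None:
    """CML prognostic scores, their agreement, and accuracy against MMR."""
    _configure_logging(log_level)
    ctx.ensure_object(dict)
    ctx.obj["seed"] = seed
    if config_path:
        with open(config_path, "r", encoding="utf-8") as fh:
            defaults = yaml.safe_load(fh) or {}
        if not isinstance(defaults, dict):
            raise click.ClickException(f"{config_path}: expected a mapping")
        ctx.default_map = defaults
    logger.info("cmlrisk %s (seed=%d)", __version__, seed)


@cli.command()
@click.option("--input", "input_path", required=True,
              type=click.Path(exists=True), help="Cohort CSV.")
@click.option("--out", "out_path", required=True, type=click.Path(),
              help="Scored cohort CSV.")
@click.option("--lenient", is_flag=True,
              help="Warn on out-of-range values instead of failing.")
def score(input_path: str, out_path: str, lenient: bool) -> None:
    """Score a cohort under all four systems."""
    try:
        cohort, log = read_cohort(input_path, strict=not lenient)
        scored = score_cohort(cohort, strict=not lenient)
    except (ValidationError, SchemaError) as exc:
        raise SystemExit(_fail(exc, EXIT_VALIDATION))
    write_cohort(scored, out_path)
    logger.info("scored %d patient(s) (%d excluded for missing MMR) -> %s",
                len(scored), log.n_excluded, out_path)


@cli.command()
@click.option("--input", "input_path", required=True,
              type=click.Path(exists=True), help="Cohort CSV.")
@click.option("--strategy", type=click.Choice(["1", "2", "both"]),
              default="both", show_default=True,
              help="Merge strategy driving the consensus/conflict partition.")
@click.option("--out", "out_path", required=True, type=click.Path(),
              help="Report path (.json or .md).")
@click.option("--format", "fmt", type=click.Choice(["md", "json"]),
              default=None, help="Report format (default: from extension).")
@click.option("--lenient", is_flag=True,
              help="Warn on out-of-range values instead of failing.")
def analyze(input_path: str, strategy: str, out_path: str,
            fmt: str | None, lenient: bool) -> None:
    """Run the consistency analysis and write a Table-style report."""
    if fmt is None:
        fmt = "json" if out_path.endswith(".json") else "md"
    try:
        cohort, log = read_cohort(input_path, strict=not lenient)
        scored = score_cohort(cohort, strict=not lenient)
        report = consistency_report(
            scored, "both" if strategy == "both" else int(strategy))
    except (ValidationError, SchemaError) as exc:
        raise SystemExit(_fail(exc, EXIT_VALIDATION))
    Path(out_path).write_text(render_report(report, fmt), encoding="utf-8")
    logger.info("analyzed %d patient(s) (%d excluded), strategy=%s -> %s",
                len(scored), log.n_excluded, strategy, out_path)


@cli.command()
@click.option("--n", "n_patients", type=int, required=True,
              help="Number of patients to simulate.")
@click.option("--association", type=float, default=1.0, show_default=True,
              help="Log-odds decrease in MMR per SD of the risk composite.")
@click.option("--baseline-mmr-rate", type=float, default=62 / 95,
              show_default=True, help="Marginal MMR achievement probability.")
@click.option("--out", "out_path", required=True, type=click.Path(),
              help="Cohort CSV.")
@click.pass_context
def simulate(ctx: click.Context, n_patients: int, association: float,
             baseline_mmr_rate: float, out_path: str) -> None:
    """Simulate a synthetic cohort with reference-cohort marginals."""
    try:
        cfg = CohortConfig(n_patients=n_patients, seed=ctx.obj["seed"],
                           association=association,
                           baseline_mmr_rate=baseline_mmr_rate)
        cohort = generate_cohort(cfg)
    except ValidationError as exc:
        raise SystemExit(_fail(exc, EXIT_VALIDATION))
    write_cohort(cohort, out_path)
    logger.info("simulated %d patient(s) -> %s", n_patients, out_path)


@cli.command()
@click.option("--targets", "targets_spec", default="builtin:table4",
              show_default=True,
              help="'builtin:table4' or a path to a targets JSON file.")
@click.option("--out", "out_path", required=True, type=click.Path(),
              help="Cohort CSV.")
@click.pass_context
def reconstruct(ctx: click.Context, targets_spec: str, out_path: str) -> None:
    """Reconstruct a patient-level cohort from aggregate target tables."""
    try:
        if targets_spec.startswith("builtin:"):
            targets = TargetTables.builtin(targets_spec.split(":", 1)[1])
        else:
            with open(targets_spec, "r", encoding="utf-8") as fh:
                targets = TargetTables.from_dict(json.load(fh))
    except (ValidationError, ValueError, OSError) as exc:
        raise SystemExit(_fail(exc, EXIT_VALIDATION))
    try:
        cohort = reconstruct_cohort(targets, seed=ctx.obj["seed"])
    except InfeasiblePatternError as exc:
        raise SystemExit(_fail(exc, EXIT_INFEASIBLE))
    except ValidationError as exc:
        raise SystemExit(_fail(exc, EXIT_VALIDATION))
    write_cohort(cohort, out_path)
    logger.info("reconstructed %d patient(s) -> %s", len(cohort), out_path)


def _fail(exc: Exception, code: int) -> int:
    logger.error("%s", exc)
    click.echo(f"error: {exc}", err=True)
    return code


if __name__ == "__main__":       # pragma: no cover
    cli()
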