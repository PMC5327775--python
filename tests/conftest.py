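import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cmlrisk as cr

settings.register_profile("ci", max_examples=50, deadline=None,
                          derandomize=True)
settings.load_profile("ci")


def make_patient(**overrides) -> cr.PatientBaseline:
    """A mid-range patient; override individual fields per test."""
    base = dict(patient_id="P1", age=40.0, spleen=8.0, platelets=500.0,
                blasts=1.5, eosinophils=1.0, basophils=1.0)
    base.update(overrides)
    return cr.PatientBaseline(**base)


def make_scored_frame(cats, mmr):
    """Scored-cohort frame from explicit per-patient category tuples.

    ``cats`` is a list of (sokal, hasford, eutos, elts) category names;
    score values are placeholders (the consistency analysis only reads the
    categories and the MMR flag).
    """
    rows = []
    for i, (tup, flag) in enumerate(zip(cats, mmr)):
        row = {"patient_id": f"T{i}", "mmr_achieved": int(flag)}
        for system, cat in zip(cr.SYSTEMS, tup):
            row[f"{system.value.lower()}_value"] = 0.0
            row[f"{system.value.lower()}_cat"] = cr.RiskCategory(cat).value
        rows.append(row)
    return pd.DataFrame(rows)


def random_scored_frame(rng, n=None):
    """Random labelled cohort for property tests (categories + outcomes)."""
    n = n or int(rng.integers(5, 80))
    cats = []
    for _ in range(n):
        tup = [rng.choice(["LOW", "INTERMEDIATE", "HIGH"]),
               rng.choice(["LOW", "INTERMEDIATE", "HIGH"]),
               rng.choice(["LOW", "HIGH"]),
               rng.choice(["LOW", "INTERMEDIATE", "HIGH"])]
        cats.append(tup)
    return make_scored_frame(cats, rng.integers(0, 2, n))


@pytest.fixture(scope="session")
def builtin_targets():
    return cr.TargetTables.builtin()


@pytest.fixture(scope="session")
def reconstructed(builtin_targets):
    return cr.reconstruct_cohort(builtin_targets, seed=20260919)


@pytest.fixture(scope="session")
def reconstructed_scored(reconstructed):
    return cr.score_cohort(reconstructed)


@pytest.fixture(scope="session")
def reconstructed_report(reconstructed_scored):
    return cr.consistency_report(reconstructed_scored, "both")
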