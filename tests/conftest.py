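"""Shared fixtures: reduced-protocol synthetic cohorts reused across tests.

The reduced protocol keeps the full gesture set and all four rounds but
one set per round, which preserves every structural property (round-based
calibration, transitions, round splits) at a fraction of the samples.
"""

from __future__ import annotations

from functools import lru_cache

import pytest

from emgkit import SubjectProfile, build_schedule, make_cohort
from emgkit.pipeline import subject_dataset


@lru_cache(maxsize=4)
def cohort_tables_for_seed(seed: int):
    """Balanced feature tables for a 3-subject reduced-protocol cohort."""
    schedule = build_schedule(rounds=4, sets_per_round=1)
    cohort = make_cohort(
        3, SubjectProfile(), variability=0.2, seed=100 + seed, schedule=schedule
    )
    return {
        rec.subject_id: subject_dataset(rec, seed=seed) for _, rec in cohort
    }


@pytest.fixture(scope="session")
def cohort_tables():
    """The seed-0 cohort (3 subjects)."""
    return cohort_tables_for_seed(0)


@pytest.fixture(scope="session")
def subject_table(cohort_tables):
    """One subject's balanced feature table."""
    return cohort_tables["S01"]
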