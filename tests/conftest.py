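"""Shared fixtures: handcrafted proband builders and a mid-sized synthetic
cohort reused by the statistical tests."""

from __future__ import annotations

import datetime

import pytest

from historyweight import (
    CancerDiagnosis,
    ClinicalHistory,
    Degree,
    Ethnicity,
    FindingClass,
    Gene,
    Proband,
    RelativeDiagnosis,
    SimCohortConfig,
    Site,
    generate_cohort,
)


def make_proband(
    pid: str,
    date: str = "2014-06-01",
    ethnicity: Ethnicity = Ethnicity.EUROPEAN,
    age: int = 50,
    personal=(),
    relatives=(),
    findings=None,
    missing: bool = False,
) -> Proband:
    personal = tuple(
        CancerDiagnosis(Site(s), a) if not isinstance(s, Site) else CancerDiagnosis(s, a)
        for s, a in personal
    )
    relatives = tuple(
        RelativeDiagnosis(Degree(d), Site(s), a) for d, s, a in relatives
    )
    history = ClinicalHistory(
        current_age=age,
        personal=() if missing else personal,
        relatives=() if missing else relatives,
        missing=missing,
    )
    return Proband(
        proband_id=pid,
        test_date=datetime.date.fromisoformat(date),
        ethnicity=ethnicity,
        history=history,
        findings={Gene(g): FindingClass(c) for g, c in (findings or {}).items()},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """6,000-proband synthetic cohort with truth, shared across tests."""
    return generate_cohort(SimCohortConfig(n_probands=6000, seed=101))


@pytest.fixture(scope="session")
def small_probands(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return small_cohort[1]
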