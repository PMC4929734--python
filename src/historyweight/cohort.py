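"""Domain model for a hereditary-cancer testing cohort.

One tested individual (a *proband*) is described by the clinical intake
record: current age, ethnicity, test date, personal cancer diagnoses,
affected-relative diagnoses, and the per-gene molecular finding from the
test itself.  A *variant observation* links a variant in one of the
mismatch-repair genes MLH1/MSH2/MSH6 to the ordered list of probands that
carry it.  The module also implements the eligibility filter applied
before any history weighting: probands are dropped when no history was
provided, when they are personally affected with a rare Lynch-associated
cancer (too little reference data to model), or when they carry a
pathogenic mutation or VUS in a Lynch gene other than the one under
analysis.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import EmptyCohortError

__all__ = [
    "Gene",
    "Site",
    "Degree",
    "Ethnicity",
    "FindingClass",
    "SCORED_SITES",
    "CancerDiagnosis",
    "RelativeDiagnosis",
    "ClinicalHistory",
    "Proband",
    "VariantObservation",
    "GeneConfig",
    "DEFAULT_GENE_CONFIGS",
    "filter_eligible",
    "validate_cohort",
    "Violation",
]


class Gene(str, enum.Enum):
    MLH1 = "MLH1"
    MSH2 = "MSH2"
    MSH6 = "MSH6"


class Site(str, enum.Enum):
    """Cancer site category as recorded on the test request form.

    ``colorectal``, ``endometrial`` and ``ovarian`` are the Lynch cancers
    the algorithm scores.  ``other_lynch`` covers the rare Lynch-associated
    sites (hepatic, gastric, hepatobiliary, pancreatic, small bowel,
    brain); a personal diagnosis there excludes the proband.  ``unrelated``
    covers everything else and is recorded but never scored.
    """

    COLORECTAL = "colorectal"
    ENDOMETRIAL = "endometrial"
    OVARIAN = "ovarian"
    OTHER_LYNCH = "other_lynch"
    UNRELATED = "unrelated"


#: Sites that contribute to the history discretization.
SCORED_SITES = (Site.COLORECTAL, Site.ENDOMETRIAL, Site.OVARIAN)


class Degree(str, enum.Enum):
    FIRST = "first"
    SECOND = "second"


class Ethnicity(str, enum.Enum):
    """Closed ethnicity categories used for control matching only."""

    EUROPEAN = "european"
    AFRICAN = "african"
    HISPANIC = "hispanic"
    ASIAN = "asian"
    ASHKENAZI = "ashkenazi"
    OTHER = "other"
    UNSPECIFIED = "unspecified"


class FindingClass(str, enum.Enum):
    """Per-gene molecular result of the test."""

    PATHOGENIC = "pathogenic"
    VUS = "vus"
    BENIGN_ONLY = "benign_only"
    NONE = "none"


_AGE_MIN, _AGE_MAX = 1, 100


def _check_age(age: int, what: str) -> None:
    if not isinstance(age, int) or isinstance(age, bool):
        raise TypeError(f"{what} must be an integer, got {age!r}")
    if not _AGE_MIN <= age <= _AGE_MAX:
        raise ValueError(f"{what} must be in [{_AGE_MIN}, {_AGE_MAX}], got {age}")


@dataclass(frozen=True, slots=True)
class CancerDiagnosis:
    site: Site
    age_at_diagnosis: int

    def __post_init__(self) -> None:
        if not isinstance(self.site, Site):
            object.__setattr__(self, "site", Site(self.site))
        _check_age(self.age_at_diagnosis, "age_at_diagnosis")


@dataclass(frozen=True, slots=True)
class RelativeDiagnosis:
    degree: Degree
    site: Site
    age_at_diagnosis: int

    def __post_init__(self) -> None:
        if not isinstance(self.degree, Degree):
            object.__setattr__(self, "degree", Degree(self.degree))
        if not isinstance(self.site, Site):
            object.__setattr__(self, "site", Site(self.site))
        _check_age(self.age_at_diagnosis, "age_at_diagnosis")


@dataclass(frozen=True, slots=True)
class ClinicalHistory:
    """Personal and family cancer history of one proband.

    ``missing=True`` means history was not provided on the intake form, in
    which case both diagnosis lists must be empty and the proband is
    excluded from analysis.
    """

    current_age: int
    personal: tuple[CancerDiagnosis, ...] = ()
    relatives: tuple[RelativeDiagnosis, ...] = ()
    missing: bool = False

    def __post_init__(self) -> None:
        _check_age(self.current_age, "current_age")
        object.__setattr__(self, "personal", tuple(self.personal))
        object.__setattr__(self, "relatives", tuple(self.relatives))
        if self.missing and (self.personal or self.relatives):
            raise ValueError("a missing history cannot carry diagnoses")


@dataclass(frozen=True, slots=True)
class Proband:
    proband_id: str
    test_date: datetime.date
    ethnicity: Ethnicity
    history: ClinicalHistory
    findings: Mapping[Gene, FindingClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.ethnicity, Ethnicity):
            object.__setattr__(self, "ethnicity", Ethnicity(self.ethnicity))
        if not isinstance(self.test_date, datetime.date):
            raise TypeError("test_date must be a datetime.date")
        findings = {Gene(g): FindingClass(c) for g, c in dict(self.findings).items()}
        object.__setattr__(self, "findings", findings)

    def finding(self, gene: Gene) -> FindingClass:
        return self.findings.get(gene, FindingClass.NONE)


@dataclass(frozen=True, slots=True)
class VariantObservation:
    """A variant together with its carrier probands.

    ``carrier_ids`` is ordered; repeated ids are only legal when the
    matching positions of ``duplicate_flags`` mark them as simulated
    duplicates (the relatedness-emulation mechanism of the simulated
    variant protocol).
    """

    variant_id: str
    gene: Gene
    carrier_ids: tuple[str, ...]
    truth_label: Optional[str] = None  # "pathogenic" | "benign" | None
    duplicate_flags: Optional[tuple[bool, ...]] = None

    def __post_init__(self) -> None:
        if not isinstance(self.gene, Gene):
            object.__setattr__(self, "gene", Gene(self.gene))
        object.__setattr__(self, "carrier_ids", tuple(self.carrier_ids))
        if not self.carrier_ids:
            raise ValueError("carrier_ids must be non-empty")
        if self.truth_label not in (None, "pathogenic", "benign"):
            raise ValueError(f"bad truth_label {self.truth_label!r}")
        flags = self.duplicate_flags
        if flags is not None:
            flags = tuple(bool(f) for f in flags)
            object.__setattr__(self, "duplicate_flags", flags)
            if len(flags) != len(self.carrier_ids):
                raise ValueError("duplicate_flags length mismatch")
        dup_ok = set()
        if flags:
            dup_ok = {cid for cid, f in zip(self.carrier_ids, flags) if f}
        seen: set[str] = set()
        for cid in self.carrier_ids:
            if cid in seen and cid not in dup_ok:
                raise ValueError(f"duplicate carrier id {cid!r} not flagged as simulated")
            seen.add(cid)


@dataclass(frozen=True, slots=True)
class GeneConfig:
    """Per-gene constants of the classification pipeline.

    ``variant_pathogenic_prevalence`` is the prior probability that a
    variant observed in this gene is pathogenic (used for PPV/NPV
    prevalence adjustment).  ``sd_benign``/``sd_pathogenic`` are the
    standard-deviation multipliers added to the ECDF percentile
    thresholds for the benign and pathogenic call directions.
    """

    gene: Gene
    prior_carrier_probability: float
    variant_pathogenic_prevalence: float
    sd_benign: float
    sd_pathogenic: float

    def __post_init__(self) -> None:
        if not isinstance(self.gene, Gene):
            object.__setattr__(self, "gene", Gene(self.gene))
        for name in ("prior_carrier_probability", "variant_pathogenic_prevalence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be strictly inside (0,1), got {v}")
        for name in ("sd_benign", "sd_pathogenic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


DEFAULT_GENE_CONFIGS: dict[Gene, GeneConfig] = {
    Gene.MLH1: GeneConfig(Gene.MLH1, 0.020, 0.242, 0.7, 2.2),
    Gene.MSH2: GeneConfig(Gene.MSH2, 0.018, 0.168, 0.9, 2.3),
    Gene.MSH6: GeneConfig(Gene.MSH6, 0.015, 0.129, 1.0, 2.2),
}


# ---------------------------------------------------------------------------
# Eligibility filter


REASON_NO_HISTORY = "no_history"
REASON_RARE_LYNCH = "rare_lynch_personal"
REASON_OTHER_GENE_FINDING = "other_gene_finding"


def exclusion_reason(proband: Proband, gene: Gene) -> Optional[str]:
    """Reason this proband is excluded from analysis of ``gene``, or None.

    Rules, in precedence order:

    1. no personal/family history provided;
    2. personally affected with a rare Lynch-associated cancer
       (``other_lynch`` site) — relatives with such cancers are retained
       (and ignored at scoring time);
    3. known pathogenic mutation or VUS in a Lynch gene other than the
       gene under analysis.
    """
    if proband.history.missing:
        return REASON_NO_HISTORY
    if any(d.site is Site.OTHER_LYNCH for d in proband.history.personal):
        return REASON_RARE_LYNCH
    for g, cls in proband.findings.items():
        if g is gene:
            continue
        if cls in (FindingClass.PATHOGENIC, FindingClass.VUS):
            return REASON_OTHER_GENE_FINDING
    return None


def filter_eligible(
    probands: Sequence[Proband], gene: Gene
) -> tuple[list[Proband], dict[str, str]]:
    """Split a cohort into (eligible probands, {proband_id: reason}).

    Eligibility depends only on the individual record, so the operation is
    idempotent and order-independent, and
    ``len(eligible) + len(exclusion_log) == len(probands)``.
    """
    if not probands:
        raise EmptyCohortError("filter_eligible requires a non-empty cohort")
    gene = Gene(gene)
    eligible: list[Proband] = []
    log: dict[str, str] = {}
    for p in probands:
        reason = exclusion_reason(p, gene)
        if reason is None:
            eligible.append(p)
        else:
            log[p.proband_id] = reason
    return eligible, log


# ---------------------------------------------------------------------------
# Cohort validation (report-only)


@dataclass(frozen=True, slots=True)
class Violation:
    proband_id: str
    kind: str  # duplicate_id | age_range | bad_date
    detail: str


def validate_cohort(probands: Sequence[Proband]) -> list[Violation]:
    """Report duplicate ids, out-of-range ages and bad dates; never mutates.

    The domain constructors already reject most malformed values, so this
    is the defence for records built by other means (e.g. ``__new__``
    round-trips or external callers bypassing ``__post_init__``).
    """
    report: list[Violation] = []
    seen: set[str] = set()
    for p in probands:
        if p.proband_id in seen:
            report.append(Violation(p.proband_id, "duplicate_id", "proband_id reused"))
        seen.add(p.proband_id)
        ages = [p.history.current_age]
        ages += [d.age_at_diagnosis for d in p.history.personal]
        ages += [d.age_at_diagnosis for d in p.history.relatives]
        for a in ages:
            if not _AGE_MIN <= a <= _AGE_MAX:
                report.append(Violation(p.proband_id, "age_range", f"age {a} outside [1,100]"))
        if not isinstance(p.test_date, datetime.date):
            report.append(Violation(p.proband_id, "bad_date", f"{p.test_date!r}"))
    return report
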