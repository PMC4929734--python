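"""Seeded generator of synthetic hereditary-cancer testing cohorts.

Real history weighting runs on a proprietary clinical testing cohort; this
module emulates the statistical structure the algorithm relies on, with
ground truth attached, so the whole pipeline is testable.  What matters
for history weighting is the carrier/non-carrier likelihood contrast, not
oncologic fidelity: disease risk is a piecewise-linear cumulative risk
curve per site, rising from an onset age to a terminal risk at age 70
(flat afterwards), with onset ages sampled by inverse CDF.  Mismatch
repair mutation carriers draw their personal and relative diagnoses from
gene-specific carrier curves (MLH1 and MSH2 markedly more penetrant than
MSH6, mirroring the clinical ordering); everyone else draws from
population baseline risk (colorectal 5 %, endometrial 2.6 % by age 70).
Risks are cohort-averaged — proband sex is not modelled.

The generator also injects the records the eligibility filter must
catch (missing histories, personal rare-Lynch cancers, extra
pathogenic/VUS findings), occasional cryptic relatedness (shared
family id + shared family history; the algorithm itself never sees
family ids), plus VUS/benign molecular findings so that control pools
have realistic membership rules to enforce.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import (
    SCORED_SITES,
    CancerDiagnosis,
    ClinicalHistory,
    Degree,
    Ethnicity,
    FindingClass,
    Gene,
    Proband,
    RelativeDiagnosis,
    Site,
    VariantObservation,
    filter_eligible,
)
from .errors import ConfigError, StratumExhaustedError

__all__ = [
    "PenetranceCurve",
    "FamilySizeDistribution",
    "SimCohortConfig",
    "SimTruthRecord",
    "generate_cohort",
    "plant_variant",
    "plant_disjoint_variants",
]


@dataclass(frozen=True, slots=True)
class PenetranceCurve:
    """Piecewise-linear cumulative risk: 0 before ``onset_age``, rising
    linearly to ``risk_by_70`` at age 70, flat afterwards."""

    risk_by_70: float
    onset_age: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk_by_70 < 1.0:
            raise ConfigError(f"risk_by_70 must be in [0,1), got {self.risk_by_70}")
        if not 0.0 < self.onset_age < 70.0:
            raise ConfigError("onset_age must lie in (0,70)")

    def cdf(self, age: float) -> float:
        frac = (age - self.onset_age) / (70.0 - self.onset_age)
        return self.risk_by_70 * min(max(frac, 0.0), 1.0)

    def age_at(self, u: float) -> float:
        """Inverse CDF: diagnosis age for cumulative mass ``u`` < risk_by_70."""
        return self.onset_age + (u / self.risk_by_70) * (70.0 - self.onset_age)


@dataclass(frozen=True, slots=True)
class FamilySizeDistribution:
    """Mean number of reported affected relatives (Poisson)."""

    carrier_mean: float = 1.4
    noncarrier_mean: float = 0.35


def _default_carrier_penetrance() -> dict[Gene, dict[Site, PenetranceCurve]]:
    return {
        Gene.MLH1: {
            Site.COLORECTAL: PenetranceCurve(0.55),
            Site.ENDOMETRIAL: PenetranceCurve(0.30),
            Site.OVARIAN: PenetranceCurve(0.08),
        },
        Gene.MSH2: {
            Site.COLORECTAL: PenetranceCurve(0.52),
            Site.ENDOMETRIAL: PenetranceCurve(0.30),
            Site.OVARIAN: PenetranceCurve(0.10),
        },
        Gene.MSH6: {
            Site.COLORECTAL: PenetranceCurve(0.20),
            Site.ENDOMETRIAL: PenetranceCurve(0.24),
            Site.OVARIAN: PenetranceCurve(0.04),
        },
    }


def _default_baseline_penetrance() -> dict[Site, PenetranceCurve]:
    return {
        Site.COLORECTAL: PenetranceCurve(0.05),
        Site.ENDOMETRIAL: PenetranceCurve(0.026),
        Site.OVARIAN: PenetranceCurve(0.013),
    }


def _default_ethnicity_weights() -> dict[Ethnicity, float]:
    return {
        Ethnicity.EUROPEAN: 0.60,
        Ethnicity.AFRICAN: 0.08,
        Ethnicity.HISPANIC: 0.12,
        Ethnicity.ASIAN: 0.06,
        Ethnicity.ASHKENAZI: 0.04,
        Ethnicity.OTHER: 0.05,
        Ethnicity.UNSPECIFIED: 0.05,
    }


def _default_exclusion_rates() -> dict[str, float]:
    return {
        "no_history": 0.02,
        "rare_lynch_personal": 0.01,
        "other_gene_finding": 0.01,
    }


@dataclass(frozen=True)
class SimCohortConfig:
    n_probands: int = 20_000
    carrier_fraction_per_gene: Mapping[Gene, float] = field(
        default_factory=lambda: {Gene.MLH1: 0.020, Gene.MSH2: 0.018, Gene.MSH6: 0.015}
    )
    carrier_penetrance: Mapping[Gene, Mapping[Site, PenetranceCurve]] = field(
        default_factory=_default_carrier_penetrance
    )
    baseline_penetrance: Mapping[Site, PenetranceCurve] = field(
        default_factory=_default_baseline_penetrance
    )
    family_size_distribution: FamilySizeDistribution = FamilySizeDistribution()
    ethnicity_weights: Mapping[Ethnicity, float] = field(
        default_factory=_default_ethnicity_weights
    )
    test_date_start: datetime.date = datetime.date(2012, 1, 1)
    test_date_end: datetime.date = datetime.date(2015, 12, 31)
    relatedness_rate: float = 0.01
    exclusion_injection_rates: Mapping[str, float] = field(
        default_factory=_default_exclusion_rates
    )
    #: relative of a carrier proband inherits the mutation w.p. by degree
    relative_transmission: Mapping[Degree, float] = field(
        default_factory=lambda: {Degree.FIRST: 0.5, Degree.SECOND: 0.25}
    )
    vus_rate: float = 0.04
    benign_finding_rate: float = 0.12
    unrelated_cancer_rate: float = 0.08
    relative_other_lynch_rate: float = 0.04
    relative_reference_age: float = 75.0
    current_age_mean: float = 52.0
    current_age_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probands <= 0:
            raise ConfigError("n_probands must be positive")
        if self.test_date_start >= self.test_date_end:
            raise ConfigError("test_date_start must precede test_date_end")
        total_eth = sum(self.ethnicity_weights.values())
        if total_eth <= 0:
            raise ConfigError("ethnicity weights must have positive total")
        fractions = list(self.carrier_fraction_per_gene.values()) + [
            self.relatedness_rate,
            self.vus_rate,
            self.benign_finding_rate,
            self.unrelated_cancer_rate,
            self.relative_other_lynch_rate,
            *self.exclusion_injection_rates.values(),
        ]
        for f in fractions:
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"fraction {f} outside [0,1]")
        if sum(self.carrier_fraction_per_gene.values()) >= 1.0:
            raise ConfigError("carrier fractions must sum below 1")


@dataclass(frozen=True, slots=True)
class SimTruthRecord:
    proband_id: str
    true_carrier_gene: Optional[Gene]
    family_id: str


def _draw_personal(
    rng: np.random.Generator,
    curves: Mapping[Site, PenetranceCurve],
    current_age: int,
) -> list[CancerDiagnosis]:
    out = []
    for site in SCORED_SITES:
        curve = curves[site]
        u = rng.random()
        if u < curve.cdf(current_age):
            age = int(round(curve.age_at(u)))
            age = max(1, min(age, current_age, 100))
            out.append(CancerDiagnosis(site, age))
    return out


def _draw_relative(
    rng: np.random.Generator,
    config: SimCohortConfig,
    carrier_gene: Optional[Gene],
) -> Optional[RelativeDiagnosis]:
    degree = Degree.FIRST if rng.random() < 0.7 else Degree.SECOND
    if rng.random() < config.relative_other_lynch_rate:
        return RelativeDiagnosis(degree, Site.OTHER_LYNCH, int(rng.integers(35, 81)))
    if carrier_gene is not None and rng.random() < config.relative_transmission[degree]:
        curves = config.carrier_penetrance[carrier_gene]
    else:
        curves = config.baseline_penetrance
    ref = config.relative_reference_age
    weights = np.array([curves[s].cdf(ref) for s in SCORED_SITES])
    total = weights.sum()
    if total <= 0:
        return None
    site = SCORED_SITES[rng.choice(len(SCORED_SITES), p=weights / total)]
    curve = curves[site]
    u = rng.random() * curve.cdf(ref)
    age = int(round(curve.age_at(u)))
    return RelativeDiagnosis(degree, site, max(1, min(age, 100)))


def generate_cohort(
    config: SimCohortConfig,
) -> tuple[list[Proband], list[SimTruthRecord]]:
    """Generate a testing cohort with ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_probands
    genes = list(config.carrier_fraction_per_gene)
    eth_cats = list(config.ethnicity_weights)
    eth_w = np.array([config.ethnicity_weights[e] for e in eth_cats], dtype=float)
    eth_w = eth_w / eth_w.sum()

    span_days = (config.test_date_end - config.test_date_start).days
    eth_idx = rng.choice(len(eth_cats), size=n, p=eth_w)
    date_off = rng.integers(0, span_days + 1, size=n)
    ages = np.clip(
        np.round(rng.normal(config.current_age_mean, config.current_age_sd, size=n)),
        19,
        90,
    ).astype(int)

    carrier_u = rng.random(n)
    cum = np.cumsum([config.carrier_fraction_per_gene[g] for g in genes])
    carrier_gene_idx = np.searchsorted(cum, carrier_u)  # == len(genes) -> non-carrier

    rates = config.exclusion_injection_rates
    missing_flag = rng.random(n) < rates.get("no_history", 0.0)
    rare_flag = rng.random(n) < rates.get("rare_lynch_personal", 0.0)
    extra_finding_flag = rng.random(n) < rates.get("other_gene_finding", 0.0)
    vus_flag = rng.random(n) < config.vus_rate
    benign_flag = rng.random(n) < config.benign_finding_rate
    unrelated_flag = rng.random(n) < config.unrelated_cancer_rate
    related_flag = rng.random(n) < config.relatedness_rate
    related_flag[0] = False

    probands: list[Proband] = []
    truth: list[SimTruthRecord] = []
    family_ids: list[str] = []
    carrier_of: list[Optional[Gene]] = []
    fam = config.family_size_distribution

    for i in range(n):
        pid = f"P{i:06d}"
        gene = genes[carrier_gene_idx[i]] if carrier_gene_idx[i] < len(genes) else None
        family_id = f"F{i:06d}"
        shared_relatives: Optional[tuple[RelativeDiagnosis, ...]] = None
        if related_flag[i]:
            partner = int(rng.integers(0, i))
            family_id = family_ids[partner]
            partner_gene = carrier_of[partner]
            gene = partner_gene if (partner_gene is not None and rng.random() < 0.5) else None
            shared_relatives = probands[partner].history.relatives

        findings: dict[Gene, FindingClass] = {}
        if gene is not None:
            findings[gene] = FindingClass.PATHOGENIC
        if vus_flag[i]:
            g = Gene(list(Gene)[rng.integers(0, len(Gene))])
            findings.setdefault(g, FindingClass.VUS)
        if benign_flag[i]:
            g = Gene(list(Gene)[rng.integers(0, len(Gene))])
            findings.setdefault(g, FindingClass.BENIGN_ONLY)
        if extra_finding_flag[i]:
            free = [g for g in Gene if g not in findings or findings[g] is FindingClass.BENIGN_ONLY]
            if free:
                findings[free[int(rng.integers(0, len(free)))]] = FindingClass.VUS

        current_age = int(ages[i])
        if missing_flag[i]:
            history = ClinicalHistory(current_age=current_age, missing=True)
        else:
            curves = (
                config.carrier_penetrance[gene] if gene is not None else config.baseline_penetrance
            )
            personal = _draw_personal(rng, curves, current_age)
            if unrelated_flag[i] and current_age > 26:
                personal.append(
                    CancerDiagnosis(Site.UNRELATED, int(rng.integers(25, current_age)))
                )
            if rare_flag[i] and current_age > 31:
                personal.append(
                    CancerDiagnosis(Site.OTHER_LYNCH, int(rng.integers(30, current_age)))
                )
            if shared_relatives is not None:
                relatives = shared_relatives
            else:
                mean = fam.carrier_mean if gene is not None else fam.noncarrier_mean
                n_rel = min(int(rng.poisson(mean)), 6)
                rels = []
                for _ in range(n_rel):
                    r = _draw_relative(rng, config, gene)
                    if r is not None:
                        rels.append(r)
                relatives = tuple(rels)
            history = ClinicalHistory(
                current_age=current_age, personal=tuple(personal), relatives=relatives
            )

        probands.append(
            Proband(
                proband_id=pid,
                test_date=config.test_date_start + datetime.timedelta(days=int(date_off[i])),
                ethnicity=eth_cats[eth_idx[i]],
                history=history,
                findings=findings,
            )
        )
        truth.append(SimTruthRecord(pid, gene, family_id))
        family_ids.append(family_id)
        carrier_of.append(gene)

    return probands, truth


# ---------------------------------------------------------------------------
# Variant planting


def _stratum(
    probands: Sequence[Proband],
    truth: Sequence[SimTruthRecord],
    gene: Gene,
    label: str,
) -> list[Proband]:
    eligible, _ = filter_eligible(probands, gene)
    truth_map = {t.proband_id: t.true_carrier_gene for t in truth}
    if label == "pathogenic":
        return [p for p in eligible if truth_map.get(p.proband_id) is gene]
    if label == "benign":
        return [
            p
            for p in eligible
            if truth_map.get(p.proband_id) is None
            and all(
                c not in (FindingClass.PATHOGENIC, FindingClass.VUS)
                for c in p.findings.values()
            )
        ]
    raise ValueError(f"label must be 'pathogenic' or 'benign', got {label!r}")


def plant_variant(
    probands: Sequence[Proband],
    truth: Sequence[SimTruthRecord],
    gene: Gene,
    label: str,
    n_carriers: int,
    seed: int,
) -> VariantObservation:
    """Plant a variant whose carriers are sampled from the truth stratum.

    Pathogenic variants draw from eligible true carriers of ``gene``;
    benign variants from eligible non-carriers with no pathogenic/VUS
    finding anywhere.  Carriers are sampled without replacement and
    returned ordered by test date.
    """
    gene = Gene(gene)
    stratum = _stratum(probands, truth, gene, label)
    if len(stratum) < n_carriers:
        raise StratumExhaustedError(
            f"need {n_carriers} {label} probands for {gene.value}, have {len(stratum)}"
        )
    rng = np.random.default_rng(seed)
    chosen = [stratum[j] for j in rng.choice(len(stratum), size=n_carriers, replace=False)]
    chosen.sort(key=lambda p: (p.test_date, p.proband_id))
    return VariantObservation(
        variant_id=f"planted_{gene.value}_{label}_{seed}",
        gene=gene,
        carrier_ids=tuple(p.proband_id for p in chosen),
        truth_label=label,
    )


def plant_disjoint_variants(
    probands: Sequence[Proband],
    truth: Sequence[SimTruthRecord],
    gene: Gene,
    label: str,
    sizes: Sequence[int],
    seed: int,
) -> list[VariantObservation]:
    """Plant several variants with mutually disjoint carrier sets.

    Stands in for the laboratory's observed true variants when building
    simulated-variant source sets: the stratum is shuffled once and cut
    into consecutive chunks of the requested sizes.
    """
    gene = Gene(gene)
    stratum = _stratum(probands, truth, gene, label)
    need = int(np.sum(sizes))
    if len(stratum) < need:
        raise StratumExhaustedError(
            f"need {need} {label} probands for {gene.value}, have {len(stratum)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(stratum))
    out = []
    pos = 0
    for k, size in enumerate(sizes):
        chunk = [stratum[j] for j in order[pos : pos + size]]
        pos += size
        chunk.sort(key=lambda p: (p.test_date, p.proband_id))
        out.append(
            VariantObservation(
                variant_id=f"planted_{gene.value}_{label}_{seed}_{k}",
                gene=gene,
                carrier_ids=tuple(p.proband_id for p in chunk),
                truth_label=label,
            )
        )
    return out
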