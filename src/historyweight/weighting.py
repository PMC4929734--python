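"""Conditional probability tables, likelihood ratios, and the history
weighting score.

The probability that a tested proband carries a pathogenic mutation in a
given gene, conditional on a discretized summary of their personal and
family cancer history, is estimated from observed proportions in a
reference cohort and stored in a gene-specific conditional probability
table.  For a proband falling in cell with carrier probability ``q``
against a cohort prior ``pi``, the likelihood ratio is the ratio of the
posterior to the prior odds of *not* carrying a pathogenic mutation:

    LR = [(1 - q) / q] / [(1 - pi) / pi]

so probands with carrier-enriched histories (q > pi) contribute LR < 1
and evidence of pathogenicity accumulates as a negative log score.  The
variant-level history weighting score is the product of carrier LRs
(log-additive), restricted to the 100 most recent carriers by test date.

Discretization scheme (``HistoryBinKey``): per scored site (colorectal,
endometrial, ovarian) the personal stratum is unaffected or the age bin
of the earliest diagnosis in {<35, 35-49, 50-64, >=65}; the family
stratum is the count of affected relatives capped at 3 crossed with the
age bin of the earliest relative onset; plus the proband's current-age
bin.  Any fixed, total, finite discretization preserves the algorithm's
logic; this one is deliberately coarse enough to be estimable from tens
of thousands of probands.  Unrelated and rare-Lynch-site diagnoses are
ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from .cohort import (
    SCORED_SITES,
    ClinicalHistory,
    FindingClass,
    Gene,
    Proband,
    VariantObservation,
)
from .errors import (
    DegenerateTableError,
    IneligibleProbandError,
    InsufficientProbandsError,
)

__all__ = [
    "AGE_BIN_EDGES",
    "age_bin",
    "HistoryBinKey",
    "bin_history",
    "CellStats",
    "ConditionalProbabilityTable",
    "ScoringPolicy",
    "LikelihoodRatio",
    "likelihood_ratio",
    "VariantScore",
    "estimate_table",
    "history_weighting_score",
]

#: Age bin boundaries: <35, 35-49, 50-64, >=65.
AGE_BIN_EDGES = (35, 50, 65)

#: Cap on the per-site count of affected relatives.
RELATIVE_COUNT_CAP = 3


def age_bin(age: int) -> int:
    """Index of ``age`` in the bins <35, 35-49, 50-64, >=65."""
    b = 0
    for edge in AGE_BIN_EDGES:
        if age >= edge:
            b += 1
    return b


class HistoryBinKey(NamedTuple):
    """Discretized clinical history; the key space is finite and total.

    Personal codes: 0 = unaffected with that site, otherwise
    1 + age_bin(earliest diagnosis).  Family codes: 0 = no affected
    relatives with that site, otherwise
    1 + (min(count,3) - 1) * 4 + age_bin(earliest relative onset).
    """

    age_bin: int
    crc: int
    ec: int
    ov: int
    fam_crc: int
    fam_ec: int
    fam_ov: int


def _personal_code(history: ClinicalHistory, site) -> int:
    ages = [d.age_at_diagnosis for d in history.personal if d.site is site]
    if not ages:
        return 0
    return 1 + age_bin(min(ages))


def _family_code(history: ClinicalHistory, site) -> int:
    ages = [d.age_at_diagnosis for d in history.relatives if d.site is site]
    if not ages:
        return 0
    count = min(len(ages), RELATIVE_COUNT_CAP)
    return 1 + (count - 1) * 4 + age_bin(min(ages))


def bin_history(history: ClinicalHistory) -> HistoryBinKey:
    """Map an eligible history to its bin key.

    Total on eligible histories; raises :class:`IneligibleProbandError`
    for a missing history.  ``unrelated`` and ``other_lynch`` sites never
    influence the key.
    """
    if history.missing:
        raise IneligibleProbandError("cannot bin a missing history")
    crc, ec, ov = (_personal_code(history, s) for s in SCORED_SITES)
    fcrc, fec, fov = (_family_code(history, s) for s in SCORED_SITES)
    return HistoryBinKey(age_bin(history.current_age), crc, ec, ov, fcrc, fec, fov)


# ---------------------------------------------------------------------------
# Tables and scores


class CellStats(NamedTuple):
    carrier_count: int
    total_count: int
    q: float  # smoothed carrier probability


@dataclass(frozen=True, slots=True)
class ScoringPolicy:
    """Caps and smoothing of the history weighting score."""

    max_probands: int = 100
    min_probands: int = 5
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.min_probands > self.max_probands:
            raise ValueError("min_probands must be <= max_probands")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass(frozen=True)
class ConditionalProbabilityTable:
    """Gene-specific map from history bin to smoothed carrier probability.

    ``prior`` is the overall carrier fraction pi of the reference cohort;
    cells never observed fall back to pi (likelihood ratio 1).
    """

    gene: Gene
    cells: Mapping[HistoryBinKey, CellStats]
    prior: float
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must be strictly inside (0,1)")
        for key, cell in self.cells.items():
            if not 0.0 < cell.q < 1.0:
                raise ValueError(f"cell {key} has q outside (0,1)")
            if cell.total_count < cell.carrier_count:
                raise ValueError(f"cell {key} has total < carriers")

    def q_for(self, key: HistoryBinKey) -> float:
        cell = self.cells.get(key)
        return self.prior if cell is None else cell.q

    def log_lr_for(self, key: HistoryBinKey) -> float:
        return likelihood_ratio(self.q_for(key), self.prior).log_value

    def log_lr_for_history(self, history: ClinicalHistory) -> float:
        return self.log_lr_for(bin_history(history))


class LikelihoodRatio(NamedTuple):
    value: float
    log_value: float


def likelihood_ratio(q: float, prior: float) -> LikelihoodRatio:
    """LR = posterior odds / prior odds of *not* carrying a mutation.

    ``q`` is the posterior carrier probability for the proband's history
    cell and ``prior`` the cohort carrier probability; both must lie
    strictly inside (0,1) (smoothing guarantees this for table cells).
    """
    for name, v in (("q", q), ("prior", prior)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be strictly inside (0,1), got {v}")
    value = ((1.0 - q) / q) / ((1.0 - prior) / prior)
    return LikelihoodRatio(value, math.log(value))


class VariantScore(NamedTuple):
    log_hws: float
    n_used: int
    proband_ids_used: tuple[str, ...]


def estimate_table(
    eligible_probands: Sequence[Proband],
    gene: Gene,
    policy: ScoringPolicy = ScoringPolicy(),
) -> ConditionalProbabilityTable:
    """Estimate the conditional probability table from a reference cohort.

    A proband counts as a carrier when its molecular finding for ``gene``
    is pathogenic.  Cell probabilities are smoothed symmetrically:
    q = (carriers + c) / (total + 2c) with pseudocount c, which keeps
    every likelihood ratio finite.
    """
    gene = Gene(gene)
    counts: dict[HistoryBinKey, list[int]] = {}
    n_carriers = 0
    total = 0
    for p in eligible_probands:
        key = bin_history(p.history)
        carrier = p.finding(gene) is FindingClass.PATHOGENIC
        cell = counts.setdefault(key, [0, 0])
        cell[0] += int(carrier)
        cell[1] += 1
        n_carriers += int(carrier)
        total += 1
    if total == 0:
        raise DegenerateTableError("no eligible probands")
    if n_carriers == 0 or n_carriers == total:
        raise DegenerateTableError(
            f"need both carriers and non-carriers for {gene.value}: "
            f"{n_carriers}/{total} carriers"
        )
    c = policy.pseudocount
    cells = {
        key: CellStats(k, n, (k + c) / (n + 2.0 * c)) for key, (k, n) in counts.items()
    }
    return ConditionalProbabilityTable(gene, cells, n_carriers / total, c)


def _recency_order(entries: Iterable[tuple[str, "object"]]):
    # Most recent test_date first; date ties broken by proband_id
    # lexicographic order so the selection is deterministic.  Two stable
    # sorts: id ascending, then date descending.
    by_id = sorted(entries, key=lambda e: e[0])
    return sorted(by_id, key=lambda e: e[1], reverse=True)


def history_weighting_score(
    observation: VariantObservation,
    probands: Mapping[str, Proband],
    table: ConditionalProbabilityTable,
    policy: ScoringPolicy = ScoringPolicy(),
) -> VariantScore:
    """Log history weighting score of a variant.

    Sums the log likelihood ratios of the ``min(n, max_probands)``
    carrier observations with the latest test dates (simulated duplicates
    contribute once per appearance).  The result is invariant to the
    order of ``observation.carrier_ids``.  Raises
    :class:`InsufficientProbandsError` below ``policy.min_probands``
    observations; the caller decides how to surface that.
    """
    entries = [(cid, probands[cid].test_date) for cid in observation.carrier_ids]
    if len(entries) < policy.min_probands:
        raise InsufficientProbandsError(
            f"{len(entries)} carrier observations < minimum {policy.min_probands}"
        )
    selected = _recency_order(entries)[: policy.max_probands]
    log_hws = 0.0
    ids = []
    for cid, _ in selected:
        log_hws += table.log_lr_for_history(probands[cid].history)
        ids.append(cid)
    return VariantScore(log_hws, len(ids), tuple(ids))
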