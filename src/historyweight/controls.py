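"""Matched composite-control construction and ECDF statistics.

The two-hypothesis test compares a variant's log history weighting score
against two null distributions: composite pseudo-variants assembled from
probands known to carry pathogenic mutations in the gene (positive
controls) and from probands carrying benign or no variants (negative
controls).  For each carrier of the variant of interest, a pool of at
least ``min_controls_per_proband`` control individuals is accumulated in
precedence order — ethnicity-matched within +/-180 days of the carrier's
test date, then ethnicity-unmatched in the same window, then both again
in each successive +/-180-day expansion — because time-of-testing
ascertainment biases dominate ethnicity biases.  Each of the
``n_composites`` replicates draws one control per carrier uniformly at
random and sums their log likelihood ratios; the resulting empirical
distribution supplies the percentile and standard-deviation thresholds
of the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import Ethnicity, FindingClass, Gene, Proband
from .errors import PoolExhaustedError
from .weighting import ConditionalProbabilityTable

__all__ = [
    "MatchingPolicy",
    "PoolEntry",
    "select_matched_controls",
    "ControlDistribution",
    "ecdf_percentile",
    "composite_scores",
    "build_composites",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class MatchingPolicy:
    window_halfwidth_days: int = 180
    min_controls_per_proband: int = 100
    n_composites: int = 10_000

    def __post_init__(self) -> None:
        for name in ("window_halfwidth_days", "min_controls_per_proband", "n_composites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True, slots=True)
class PoolEntry:
    """Control pool accumulated for one carrier proband."""

    proband_id: str
    control_ids: tuple[str, ...]
    matched: tuple[bool, ...]  # ethnicity-matched?
    generation: tuple[int, ...]  # window expansion index (0 = first window)
    exhausted: bool  # pool ran dry below the policy minimum


def accumulate_pool(
    dates: np.ndarray,
    eth_codes: np.ndarray,
    target_date: int,
    target_eth: Optional[int],
    policy: MatchingPolicy,
    exclude: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Core matched-pool accumulation over date-sorted candidate arrays.

    ``dates`` must be sorted ascending (integer day ordinals) and aligned
    with ``eth_codes``.  ``target_eth=None`` means the carrier did not
    specify ancestry, in which case every candidate counts as unmatched
    from the first window on.  Returns (indices into the candidate
    arrays, matched flags, generation indices, exhausted flag); candidate
    accumulation stops as soon as the running pool holds at least
    ``policy.min_controls_per_proband`` members after a precedence step.
    """
    n = len(dates)
    taken = np.zeros(n, dtype=bool)
    if exclude is not None:
        taken[exclude] = True
    chunks: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    gens: list[np.ndarray] = []
    held = 0
    minimum = policy.min_controls_per_proband
    g = 0
    while True:
        w = (g + 1) * policy.window_halfwidth_days
        lo = int(np.searchsorted(dates, target_date - w, side="left"))
        hi = int(np.searchsorted(dates, target_date + w, side="right"))
        window = np.arange(lo, hi)
        new = window[~taken[lo:hi]]
        if target_eth is not None:
            is_match = eth_codes[new] == target_eth
            steps = [(new[is_match], True), (new[~is_match], False)]
        else:
            steps = [(new, False)]
        stop = False
        for idxs, matched in steps:
            if held >= minimum:
                stop = True
                break
            if len(idxs):
                taken[idxs] = True
                chunks.append(idxs)
                flags.append(np.full(len(idxs), matched))
                gens.append(np.full(len(idxs), g))
                held += len(idxs)
        if held >= minimum or stop:
            break
        if lo == 0 and hi == n:  # whole candidate set covered, nothing left
            break
        g += 1
    if chunks:
        idx = np.concatenate(chunks)
        mat = np.concatenate(flags)
        gen = np.concatenate(gens)
    else:
        idx = np.empty(0, dtype=int)
        mat = np.empty(0, dtype=bool)
        gen = np.empty(0, dtype=int)
    exhausted = held < minimum
    return idx, mat, gen, exhausted


def _is_positive_control(p: Proband, gene: Gene) -> bool:
    return p.finding(gene) is FindingClass.PATHOGENIC


def _is_negative_control(p: Proband) -> bool:
    return all(
        cls not in (FindingClass.PATHOGENIC, FindingClass.VUS)
        for cls in p.findings.values()
    )


def select_matched_controls(
    proband: Proband,
    pool: Sequence[Proband],
    kind: str,
    gene: Gene,
    policy: MatchingPolicy = MatchingPolicy(),
) -> PoolEntry:
    """Accumulate the control pool for one carrier proband.

    ``kind`` is ``"positive"`` (controls carry pathogenic mutations in
    ``gene``) or ``"negative"`` (controls carry benign or no variants in
    every Lynch gene).  The proband itself never enters its own pool.
    """
    gene = Gene(gene)
    if kind == "positive":
        candidates = [p for p in pool if _is_positive_control(p, gene)]
    elif kind == "negative":
        candidates = [p for p in pool if _is_negative_control(p)]
    else:
        raise ValueError(f"kind must be 'positive' or 'negative', got {kind!r}")
    candidates = [p for p in candidates if p.proband_id != proband.proband_id]
    candidates.sort(key=lambda p: (p.test_date, p.proband_id))
    dates = np.array([p.test_date.toordinal() for p in candidates], dtype=np.int64)
    eths = np.array([_ETH_CODE[p.ethnicity] for p in candidates], dtype=np.int64)
    target_eth = (
        None
        if proband.ethnicity is Ethnicity.UNSPECIFIED
        else _ETH_CODE[proband.ethnicity]
    )
    idx, mat, gen, exhausted = accumulate_pool(
        dates, eths, proband.test_date.toordinal(), target_eth, policy
    )
    if exhausted:
        logger.info(
            "control pool exhausted for proband %s (%s/%s): %d of %d",
            proband.proband_id, kind, gene.value, len(idx), policy.min_controls_per_proband,
        )
    return PoolEntry(
        proband_id=proband.proband_id,
        control_ids=tuple(candidates[i].proband_id for i in idx),
        matched=tuple(bool(m) for m in mat),
        generation=tuple(int(x) for x in gen),
        exhausted=exhausted,
    )


_ETH_CODE = {e: i for i, e in enumerate(Ethnicity)}


# ---------------------------------------------------------------------------
# Composite distributions


@dataclass(frozen=True)
class ControlDistribution:
    """Empirical distribution of composite-control log scores."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.size == 0:
            raise ValueError("a control distribution needs at least one score")
        if not np.all(np.isfinite(scores)):
            raise ValueError("composite scores must be finite")
        object.__setattr__(self, "scores", scores)

    def percentile(self, p: float) -> float:
        return ecdf_percentile(self, p)

    @property
    def sd(self) -> float:
        """Sample standard deviation (n-1 denominator) of the composites."""
        if self.scores.size < 2:
            return 0.0
        return float(np.std(self.scores, ddof=1))


def ecdf_percentile(dist, p: float) -> float:
    """Linear-interpolation empirical quantile at percent ``p`` in [0,100].

    Interpolates between order statistics with plotting position
    (k-1)/(n-1); p=0 is the minimum and p=100 the maximum, and the result
    is monotone in p.
    """
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentile must be in [0,100], got {p}")
    scores = dist.scores if isinstance(dist, ControlDistribution) else np.asarray(dist, float)
    return float(np.quantile(scores, p / 100.0, method="linear"))


def composite_scores(
    pools: Sequence[np.ndarray], n_composites: int, rng: np.random.Generator
) -> np.ndarray:
    """Sum one uniform draw per carrier pool, ``n_composites`` times.

    ``pools`` holds, per carrier of the variant, the log likelihood
    ratios of its control pool.  Draws are independent across carriers
    and replicates (controls are reused across replicates; uniqueness
    constrains pool membership, not draws).
    """
    total = np.zeros(n_composites)
    for pool in pools:
        pool = np.asarray(pool, dtype=float)
        if pool.size == 0:
            raise PoolExhaustedError("empty control pool in composite construction")
        total += pool[rng.integers(0, pool.size, n_composites)]
    return total


def build_composites(
    assignments: Sequence[PoolEntry],
    probands: Mapping[str, Proband],
    table: ConditionalProbabilityTable,
    policy: MatchingPolicy,
    seed: int,
) -> ControlDistribution:
    """Build the composite-control distribution for one variant.

    ``assignments`` holds one pool entry per carrier used in the
    variant's score (after the recency cap); composites are deterministic
    for a fixed seed.
    """
    pools = []
    for entry in assignments:
        loglrs = np.array(
            [table.log_lr_for_history(probands[cid].history) for cid in entry.control_ids]
        )
        if loglrs.size == 0:
            raise PoolExhaustedError(f"empty pool for carrier {entry.proband_id}")
        pools.append(loglrs)
    rng = np.random.default_rng(seed)
    return ControlDistribution(composite_scores(pools, policy.n_composites, rng))
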