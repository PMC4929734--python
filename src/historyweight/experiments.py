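"""Simulated-variant experiments, threshold calibration, and evaluation.

A *simulated variant* with ``n`` carriers is assembled by drawing ``n``
source variants uniformly at random from true variants of the requested
class and taking one randomly chosen carrier from each; to emulate
unknown relatedness, every carrier after the first is duplicated with
probability 0.05 (a duplicate contributes its likelihood ratio once per
appearance).  Each simulated variant is pushed through the incremental
call protocol: start from five randomly selected carriers, attempt a
call, and on NotCallable/Indeterminate grow the carrier count by 20 %
(ceiling), retaining previous selections, until a directional call
succeeds or the carriers run out.

Standard-deviation threshold multipliers are calibrated by four two-fold
cross validations (8 folds): in each fold one half of the cohort builds
the conditional probability table and control pools while simulated
variants are assembled from the other half.  A grid pair is admissible
when its across-fold mean prevalence-adjusted PPV and NPV exceed 0.9975
with no fold value below 0.996; among admissible pairs the one with the
highest *correct* directional-call rate wins (ties prefer the stricter
pair).

PPV/NPV are prevalence-adjusted: raw per-class call rates are reweighted
by the prior probability ``p`` that a variant in the gene is pathogenic
(0.242 / 0.168 / 0.129 for MLH1 / MSH2 / MSH6), so the predictive values
refer to the clinically realistic variant mix rather than the simulated
one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .classify import (
    DIRECTIONAL_CATEGORIES,
    Category,
    ClassificationResult,
    EvaluationCall,
    GeneThresholds,
    call_for_evaluation,
    classify_score,
)
from .cohort import (
    DEFAULT_GENE_CONFIGS,
    FindingClass,
    Gene,
    GeneConfig,
    Proband,
    VariantObservation,
    filter_eligible,
)
from .controls import MatchingPolicy, accumulate_pool, composite_scores, _ETH_CODE
from .errors import (
    CalibrationError,
    InsufficientProbandsError,
    PoolExhaustedError,
    StratumExhaustedError,
    UndefinedPredictiveValueError,
)
from .weighting import ConditionalProbabilityTable, ScoringPolicy, estimate_table

__all__ = [
    "SimVariantConfig",
    "TrialPolicy",
    "CalibrationGrid",
    "CalibrationResult",
    "ConfusionCounts",
    "growth_sequence",
    "make_simulated_variant",
    "CallEngine",
    "run_incremental_call",
    "run_simulated_variant_experiment",
    "run_fold_experiment",
    "calibrate_sd_thresholds",
    "true_variant_trials",
    "adjusted_ppv_npv",
    "probands_to_call_profile",
    "ProfileSummary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class SimVariantConfig:
    """Simulated-variant construction parameters.

    Default counts are the published experiment scaled down tenfold
    (25,500 pathogenic / 50,500 benign per gene becomes 2,550 / 5,050),
    preserving the pathogenic:benign mix.
    """

    duplication_probability: float = 0.05
    n_pathogenic: int = 2550
    n_benign: int = 5050
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.duplication_probability <= 1.0:
            raise ValueError("duplication_probability must be in [0,1]")


@dataclass(frozen=True, slots=True)
class TrialPolicy:
    n_trials: int = 100
    start_probands: int = 5
    growth_factor: float = 1.2
    pool_cap: int = 100

    def __post_init__(self) -> None:
        if self.growth_factor <= 1.0:
            raise ValueError("growth_factor must exceed 1")
        if self.start_probands < 1:
            raise ValueError("start_probands must be >= 1")


@dataclass(frozen=True, slots=True)
class CalibrationGrid:
    """Candidate SD multipliers; spans the clinically selected range."""

    sd_benign_values: tuple[float, ...] = (0.5, 0.7, 0.9, 1.0, 1.2)
    sd_pathogenic_values: tuple[float, ...] = (1.8, 2.0, 2.2, 2.3, 2.6, 3.0, 3.5, 4.0)

    def __post_init__(self) -> None:
        if not self.sd_benign_values or not self.sd_pathogenic_values:
            raise ValueError("grids must be non-empty")
        if min(self.sd_benign_values) < 0 or min(self.sd_pathogenic_values) < 0:
            raise ValueError("SD multipliers must be non-negative")

    def pairs(self) -> list[tuple[float, float]]:
        return [
            (b, p) for p in self.sd_pathogenic_values for b in self.sd_benign_values
        ]


@dataclass
class ConfusionCounts:
    """Tallies of truth class x evaluation call (one unit per trial)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    nocall_pathogenic: int = 0
    nocall_benign: int = 0

    @property
    def total_pathogenic(self) -> int:
        return self.tp + self.fn + self.nocall_pathogenic

    @property
    def total_benign(self) -> int:
        return self.fp + self.tn + self.nocall_benign

    def record(self, truth_label: str, call: EvaluationCall) -> None:
        if truth_label == "pathogenic":
            if call is EvaluationCall.PATHOGENIC_CALL:
                self.tp += 1
            elif call is EvaluationCall.BENIGN_CALL:
                self.fn += 1
            else:
                self.nocall_pathogenic += 1
        elif truth_label == "benign":
            if call is EvaluationCall.PATHOGENIC_CALL:
                self.fp += 1
            elif call is EvaluationCall.BENIGN_CALL:
                self.tn += 1
            else:
                self.nocall_benign += 1
        else:
            raise ValueError(f"bad truth label {truth_label!r}")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.nocall_pathogenic + other.nocall_pathogenic,
            self.nocall_benign + other.nocall_benign,
        )


def adjusted_ppv_npv(counts: ConfusionCounts, prevalence: float) -> tuple[float, float]:
    """Prevalence-adjusted positive and negative predictive values.

    With per-class call rates r_tp = tp/total_pathogenic,
    r_fp = fp/total_benign, r_tn = tn/total_benign, r_fn = fn/total_pathogenic:

        PPV = r_tp * p / (r_tp * p + r_fp * (1 - p))
        NPV = r_tn * (1 - p) / (r_tn * (1 - p) + r_fn * p)

    and NPV = 1 when no pathogenic variant was ever called benign.
    Raises :class:`UndefinedPredictiveValueError` when no call at all was
    made on one side (0/0).
    """
    p = prevalence
    if not 0.0 < p < 1.0:
        raise ValueError("prevalence must be strictly inside (0,1)")
    if counts.total_pathogenic <= 0 or counts.total_benign <= 0:
        raise UndefinedPredictiveValueError("both truth classes need trials")
    r_tp = counts.tp / counts.total_pathogenic
    r_fp = counts.fp / counts.total_benign
    r_tn = counts.tn / counts.total_benign
    r_fn = counts.fn / counts.total_pathogenic
    denom_p = r_tp * p + r_fp * (1.0 - p)
    if denom_p == 0.0:
        raise UndefinedPredictiveValueError("no pathogenic calls were made")
    ppv = r_tp * p / denom_p
    if counts.fn == 0:
        npv = 1.0
    else:
        denom_n = r_tn * (1.0 - p) + r_fn * p
        if denom_n == 0.0:
            raise UndefinedPredictiveValueError("no benign calls were made")
        npv = r_tn * (1.0 - p) / denom_n
    return ppv, npv


def growth_sequence(start: int, factor: float, limit: int) -> list[int]:
    """Proband counts visited by the incremental protocol: start, then
    repeated ceiling(count * factor), clipped at ``limit``.

    From 5 with factor 1.2: 5, 6, 8, 10, 12, 15, 18, 22, 27, 33, ...
    Empty when fewer than ``start`` probands are available.
    """
    if limit < start:
        return []
    counts = [start]
    while counts[-1] < limit:
        nxt = math.ceil(counts[-1] * factor - 1e-9)
        nxt = max(nxt, counts[-1] + 1)
        counts.append(min(nxt, limit))
    return counts


# ---------------------------------------------------------------------------
# Simulated variants


def make_simulated_variant(
    true_variants: Sequence[VariantObservation],
    label: str,
    n: int,
    config: SimVariantConfig,
    rng: Optional[np.random.Generator] = None,
    variant_id: Optional[str] = None,
) -> VariantObservation:
    """Assemble one simulated variant from true-variant carriers.

    Draws ``n`` source variants of class ``label`` without replacement,
    one randomly chosen carrier from each; every carrier after the first
    is appended twice with ``config.duplication_probability`` (flagged as
    a simulated duplicate).
    """
    pool = [v for v in true_variants if v.truth_label == label]
    if len(pool) < n:
        raise StratumExhaustedError(
            f"need {n} true {label} variants, have {len(pool)}"
        )
    genes = {v.gene for v in pool}
    if len(genes) != 1:
        raise ValueError("true_variants must all belong to one gene")
    gene = genes.pop()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    src = rng.choice(len(pool), size=n, replace=False)
    carriers: list[str] = []
    flags: list[bool] = []
    seen: set[str] = set()
    for j, si in enumerate(src):
        ids = pool[si].carrier_ids
        cid = ids[int(rng.integers(0, len(ids)))]
        carriers.append(cid)
        flags.append(cid in seen)
        seen.add(cid)
        if j > 0 and rng.random() < config.duplication_probability:
            carriers.append(cid)
            flags.append(True)
    return VariantObservation(
        variant_id=variant_id or f"sim_{gene.value}_{label}_{int(rng.integers(1 << 31))}",
        gene=gene,
        carrier_ids=tuple(carriers),
        truth_label=label,
        duplicate_flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Call engine


def _is_negative_control(p: Proband) -> bool:
    return all(
        cls not in (FindingClass.PATHOGENIC, FindingClass.VUS)
        for cls in p.findings.values()
    )


class _Stratum:
    """Date-sorted candidate arrays for one control kind."""

    def __init__(self, probands: list[Proband], table: ConditionalProbabilityTable):
        probands = sorted(probands, key=lambda p: (p.test_date, p.proband_id))
        self.ids = [p.proband_id for p in probands]
        self.dates = np.array([p.test_date.toordinal() for p in probands], dtype=np.int64)
        self.eths = np.array([_ETH_CODE[p.ethnicity] for p in probands], dtype=np.int64)
        self.loglrs = np.array(
            [table.log_lr_for_history(p.history) for p in probands], dtype=float
        )
        self.index_of = {pid: i for i, pid in enumerate(self.ids)}


class CallEngine:
    """Shared machinery for scoring variants against one reference model.

    Holds the gene's conditional probability table, the positive and
    negative control strata of the reference (eligible) probands, and a
    cache of per-carrier matched control pools, so thousands of simulated
    variants can be evaluated against the same reference cheaply.
    """

    def __init__(
        self,
        reference: Sequence[Proband],
        gene: Gene,
        table: ConditionalProbabilityTable,
        scoring_policy: ScoringPolicy = ScoringPolicy(),
        matching_policy: MatchingPolicy = MatchingPolicy(),
        n_composites: Optional[int] = None,
    ):
        self.gene = Gene(gene)
        self.table = table
        self.scoring_policy = scoring_policy
        self.matching_policy = matching_policy
        self.n_composites = int(n_composites or matching_policy.n_composites)
        pos = [p for p in reference if p.finding(self.gene) is FindingClass.PATHOGENIC]
        neg = [p for p in reference if _is_negative_control(p)]
        if not pos:
            raise PoolExhaustedError(f"no positive controls for {self.gene.value}")
        if not neg:
            raise PoolExhaustedError(f"no negative controls for {self.gene.value}")
        self._strata = {"positive": _Stratum(pos, table), "negative": _Stratum(neg, table)}
        self._pool_cache: dict[tuple[str, str], np.ndarray] = {}
        self._loglr_cache: dict[str, float] = {}
        self._exhaustion_logged = 0

    def loglr_of(self, proband: Proband) -> float:
        v = self._loglr_cache.get(proband.proband_id)
        if v is None:
            v = self.table.log_lr_for_history(proband.history)
            self._loglr_cache[proband.proband_id] = v
        return v

    def pool_for(self, proband: Proband, kind: str) -> np.ndarray:
        """Log likelihood ratios of the matched control pool (cached)."""
        key = (proband.proband_id, kind)
        pool = self._pool_cache.get(key)
        if pool is not None:
            return pool
        stratum = self._strata[kind]
        from .cohort import Ethnicity  # local to avoid cycle at import time

        target_eth = (
            None
            if proband.ethnicity is Ethnicity.UNSPECIFIED
            else _ETH_CODE[proband.ethnicity]
        )
        own = stratum.index_of.get(proband.proband_id)
        exclude = None if own is None else np.array([own])
        idx, _, _, exhausted = accumulate_pool(
            stratum.dates,
            stratum.eths,
            proband.test_date.toordinal(),
            target_eth,
            self.matching_policy,
            exclude=exclude,
        )
        if exhausted:
            self._exhaustion_logged += 1
            if self._exhaustion_logged <= 10:
                logger.info(
                    "pool below minimum for %s (%s): %d controls",
                    proband.proband_id, kind, len(idx),
                )
        if len(idx) == 0:
            raise PoolExhaustedError(f"no {kind} controls for {proband.proband_id}")
        pool = stratum.loglrs[idx]
        self._pool_cache[key] = pool
        return pool


class _IterStats(NamedTuple):
    n_used: int
    score: float
    p99: float
    p995: float
    sd_pos: float
    p05: float
    p1: float
    sd_neg: float


class IncrementalVariant:
    """One variant's lazily materialized incremental-call iterations.

    ``entries`` is the (already randomized) carrier observation sequence,
    duplicates included.  Iteration ``k`` scores the first ``counts[k]``
    observations and builds both composite distributions for them; stats
    are cached so calibration can replay the protocol under many
    threshold pairs without recomputation.  Composite randomness is keyed
    by (base_seed, iteration, side) and therefore independent of the
    order in which iterations are requested.
    """

    def __init__(
        self,
        engine: CallEngine,
        entries: Sequence[Proband],
        base_seed: int,
        trial_policy: TrialPolicy,
    ):
        self.engine = engine
        self.entries = list(entries)[: trial_policy.pool_cap]
        self.base_seed = int(base_seed)
        self.counts = growth_sequence(
            trial_policy.start_probands, trial_policy.growth_factor, len(self.entries)
        )
        self._loglr_cumsum: Optional[np.ndarray] = None
        self._stats: list[_IterStats] = []
        # running composite sums, extended as the carrier prefix grows
        self._pos_sums: Optional[np.ndarray] = None
        self._neg_sums: Optional[np.ndarray] = None
        self._sums_cover = 0  # carriers already folded into the running sums

    def _cumsum(self) -> np.ndarray:
        if self._loglr_cumsum is None:
            self._loglr_cumsum = np.cumsum(
                [self.engine.loglr_of(p) for p in self.entries]
            )
        return self._loglr_cumsum

    def stat(self, k: int) -> _IterStats:
        """Iteration-``k`` score and composite-distribution statistics.

        Composites grow with the carrier prefix: each of the replicates
        keeps a running sum and the carriers added at iteration ``k``
        contribute one fresh uniform pool draw per replicate (keyed by
        (base_seed, k, side), so laziness order never changes results).
        Each iteration's composite distribution is therefore exactly one
        independent pool draw per carrier in the prefix, as required.
        """
        while len(self._stats) <= k:
            j = len(self._stats)
            c = self.counts[j]
            score = float(self._cumsum()[c - 1])
            nc = self.engine.n_composites
            if self._pos_sums is None:
                self._pos_sums = np.zeros(nc)
                self._neg_sums = np.zeros(nc)
            new = self.entries[self._sums_cover : c]
            if new:
                rng_pos = np.random.default_rng([self.base_seed, j, 0])
                rng_neg = np.random.default_rng([self.base_seed, j, 1])
                self._pos_sums += composite_scores(
                    [self.engine.pool_for(p, "positive") for p in new], nc, rng_pos
                )
                self._neg_sums += composite_scores(
                    [self.engine.pool_for(p, "negative") for p in new], nc, rng_neg
                )
                self._sums_cover = c
            p99, p995 = np.quantile(self._pos_sums, [0.99, 0.995], method="linear")
            p05, p1 = np.quantile(self._neg_sums, [0.005, 0.01], method="linear")
            sd_pos = float(np.std(self._pos_sums, ddof=1)) if nc > 1 else 0.0
            sd_neg = float(np.std(self._neg_sums, ddof=1)) if nc > 1 else 0.0
            self._stats.append(
                _IterStats(c, score, float(p99), float(p995), sd_pos, float(p05), float(p1), sd_neg)
            )
        return self._stats[k]

    def evaluate(
        self, sd_benign: float, sd_pathogenic: float
    ) -> tuple[ClassificationResult, int]:
        """Walk the growth schedule until a directional call or exhaustion."""
        policy = self.engine.scoring_policy
        if not self.counts:
            th = GeneThresholds(0.0, 0.0, 0.0, 0.0)
            res = ClassificationResult(
                Category.INSUFFICIENT_PROBANDS, float("nan"), th, len(self.entries)
            )
            return res, len(self.entries)
        res = None
        used = self.counts[-1]
        for k, c in enumerate(self.counts):
            st = self.stat(k)
            th = GeneThresholds(
                pos_99=st.p99,
                pos_995_plus=st.p995 + sd_benign * st.sd_pos,
                neg_05_minus=st.p05 - sd_pathogenic * st.sd_neg,
                neg_1=st.p1,
            )
            res = classify_score(st.score, c, th, policy)
            if res.category in DIRECTIONAL_CATEGORIES:
                return res, c
        return res, used


def run_incremental_call(
    observation: VariantObservation,
    probands: Mapping[str, Proband],
    reference: Sequence[Proband],
    table: ConditionalProbabilityTable,
    gene_config: GeneConfig,
    trial_policy: TrialPolicy = TrialPolicy(),
    scoring_policy: ScoringPolicy = ScoringPolicy(),
    matching_policy: MatchingPolicy = MatchingPolicy(),
    n_composites: Optional[int] = None,
    seed: int = 0,
) -> tuple[ClassificationResult, int]:
    """Incremental call protocol for one variant.

    ``probands`` maps carrier ids to records; ``reference`` supplies the
    control strata (pass eligible probands).  Carrier observations are
    shuffled once with ``seed`` and consumed in growing prefixes.
    """
    rng = np.random.default_rng([seed, 101])
    order = rng.permutation(len(observation.carrier_ids))
    entries = [probands[observation.carrier_ids[i]] for i in order]
    engine = CallEngine(
        reference, observation.gene, table, scoring_policy, matching_policy, n_composites
    )
    variant = IncrementalVariant(engine, entries, seed, trial_policy)
    return variant.evaluate(gene_config.sd_benign, gene_config.sd_pathogenic)


# ---------------------------------------------------------------------------
# Fold experiments


def _partition_sources(
    stratum: list[Proband],
    gene: Gene,
    label: str,
    size_range: tuple[int, int],
    rng: np.random.Generator,
) -> list[VariantObservation]:
    """Cut a shuffled stratum into disjoint synthetic 'true' variants."""
    lo, hi = size_range
    order = rng.permutation(len(stratum))
    out = []
    pos = 0
    k = 0
    while pos + lo <= len(stratum):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(stratum) - pos)
        members = sorted(
            (stratum[i] for i in order[pos : pos + size]),
            key=lambda p: (p.test_date, p.proband_id),
        )
        out.append(
            VariantObservation(
                variant_id=f"src_{gene.value}_{label}_{k}",
                gene=gene,
                carrier_ids=tuple(p.proband_id for p in members),
                truth_label=label,
            )
        )
        pos += size
        k += 1
    return out


#: source-variant carrier counts: pathogenic true variants are rare
#: (few carriers each), benign ones common.
PATHOGENIC_SOURCE_SIZE = (2, 4)
BENIGN_SOURCE_SIZE = (20, 40)
#: cap on benign source variants per fold (bounds distinct control pools)
MAX_BENIGN_SOURCES = 60


def build_fold_variants(
    reference: Sequence[Proband],
    source_cohort: Sequence[Proband],
    gene: Gene,
    sim_config: SimVariantConfig,
    trial_policy: TrialPolicy,
    scoring_policy: ScoringPolicy = ScoringPolicy(),
    matching_policy: MatchingPolicy = MatchingPolicy(),
    n_composites: Optional[int] = None,
    seed: int = 0,
) -> list[IncrementalVariant]:
    """Build the engine and the full set of simulated variants for a fold.

    ``reference`` provides the conditional probability table;
    ``source_cohort`` provides both the carriers of the simulated
    variants and the matched control pools.  Keeping carriers and
    controls in the same half means every history — variant or control —
    is scored out-of-sample under the other half's table; drawing
    controls from the table half instead would shrink held-out carrier
    scores toward zero (unseen history cells) while leaving control
    scores fully signed, biasing pathogenic variants toward benign
    calls.  Returns lazily evaluated variants tagged with their truth
    label (``IncrementalVariant.truth_label``).
    """
    gene = Gene(gene)
    elig_ref, _ = filter_eligible(list(reference), gene)
    table = estimate_table(elig_ref, gene, scoring_policy)
    elig_src, _ = filter_eligible(list(source_cohort), gene)
    engine = CallEngine(
        elig_src, gene, table, scoring_policy, matching_policy, n_composites
    )
    rng = np.random.default_rng([seed, 11])
    path_stratum = [p for p in elig_src if p.finding(gene) is FindingClass.PATHOGENIC]
    neg_stratum = [p for p in elig_src if _is_negative_control(p)]
    path_sources = _partition_sources(
        path_stratum, gene, "pathogenic", PATHOGENIC_SOURCE_SIZE, rng
    )
    if len(neg_stratum) > MAX_BENIGN_SOURCES * BENIGN_SOURCE_SIZE[1]:
        keep = rng.choice(
            len(neg_stratum), MAX_BENIGN_SOURCES * BENIGN_SOURCE_SIZE[1], replace=False
        )
        neg_stratum = [neg_stratum[i] for i in keep]
    benign_sources = _partition_sources(
        neg_stratum, gene, "benign", BENIGN_SOURCE_SIZE, rng
    )
    if not path_sources or not benign_sources:
        raise StratumExhaustedError(f"too few source variants for {gene.value}")
    by_id = {p.proband_id: p for p in elig_src}
    variants: list[IncrementalVariant] = []
    for label, sources, count in (
        ("pathogenic", path_sources, sim_config.n_pathogenic),
        ("benign", benign_sources, sim_config.n_benign),
    ):
        n = min(trial_policy.pool_cap, len(sources))
        for i in range(count):
            obs = make_simulated_variant(
                sources, label, n, sim_config, rng, variant_id=f"sim_{gene.value}_{label}_{i}"
            )
            entries = [by_id[cid] for cid in obs.carrier_ids]
            iv = IncrementalVariant(
                engine, entries, int(rng.integers(1 << 31)), trial_policy
            )
            iv.truth_label = label  # type: ignore[attr-defined]
            variants.append(iv)
    return variants


_CALL_BY_CODE = (
    EvaluationCall.PATHOGENIC_CALL,
    EvaluationCall.BENIGN_CALL,
    EvaluationCall.NO_CALL,
)


def _tally(
    variants: Sequence[IncrementalVariant],
    sd_benign: float,
    sd_pathogenic: float,
    weak_counts: bool,
) -> tuple[ConfusionCounts, list[tuple[Gene, str, int, EvaluationCall]]]:
    """Vectorized incremental-call replay over many variants.

    Semantically identical to calling ``IncrementalVariant.evaluate`` and
    :func:`historyweight.classify.call_for_evaluation` per variant (a
    property test asserts this), but applies the decision table to whole
    iteration cohorts at once so a calibration grid can replay cheaply
    against the cached iteration statistics.
    """
    n = len(variants)
    call_code = np.full(n, 2, dtype=np.int8)  # default: no call
    used = np.zeros(n, dtype=np.int64)
    active_list = []
    for i, v in enumerate(variants):
        if v.counts:
            active_list.append(i)
        else:
            used[i] = len(v.entries)  # insufficient probands
    active = np.array(active_list, dtype=np.int64)
    min_probands = variants[0].engine.scoring_policy.min_probands if n else 0
    k = 0
    while active.size:
        rows = np.array([variants[i].stat(k) for i in active], dtype=float)
        c = rows[:, 0]
        s = rows[:, 1]
        p99, p995, sd_pos, p05, p1, sd_neg = rows[:, 2:8].T
        tpos = p995 + sd_benign * sd_pos
        tneg = p05 - sd_pathogenic * sd_neg
        weak_ok = tneg <= tpos
        enough = c >= min_probands
        path = (s < p99) & (s < tneg) & enough
        weakpath = ~path & (s >= p99) & (s <= tpos) & (s < tneg) & weak_ok & enough
        weakben = (s > tpos) & (tneg <= s) & (s <= p1) & weak_ok & enough
        benign = ~weakben & (s > tpos) & (s > p1) & enough
        stop = path | weakpath | weakben | benign
        code = np.full(active.size, 2, dtype=np.int8)
        if weak_counts:
            code[path | weakpath] = 0
            code[benign | weakben] = 1
        else:
            code[path] = 0
            code[benign] = 1
        stopped = active[stop]
        call_code[stopped] = code[stop]
        used[stopped] = c[stop].astype(np.int64)
        cont = active[~stop]
        if cont.size:
            have = np.array([len(variants[i].counts) > k + 1 for i in cont])
            done = cont[~have]
            used[done] = c[~stop][~have].astype(np.int64)
            active = cont[have]
        else:
            active = cont
        k += 1
    counts = ConfusionCounts()
    details = []
    for i, v in enumerate(variants):
        call = _CALL_BY_CODE[call_code[i]]
        counts.record(v.truth_label, call)  # type: ignore[attr-defined]
        details.append((v.engine.gene, v.truth_label, int(used[i]), call))  # type: ignore[attr-defined]
    return counts, details


def run_simulated_variant_experiment(
    reference: Sequence[Proband],
    source_cohort: Sequence[Proband],
    gene: Gene,
    sim_config: SimVariantConfig,
    trial_policy: TrialPolicy = TrialPolicy(),
    gene_config: Optional[GeneConfig] = None,
    scoring_policy: ScoringPolicy = ScoringPolicy(),
    matching_policy: MatchingPolicy = MatchingPolicy(),
    n_composites: Optional[int] = None,
    weak_counts: bool = True,
    seed: int = 0,
) -> tuple[ConfusionCounts, list[tuple[Gene, str, int, EvaluationCall]]]:
    """Full simulated-variant evaluation for one gene.

    Builds tables and control pools from ``reference``, assembles
    simulated variants from ``source_cohort`` and runs the incremental
    protocol on each; the two cohorts may coincide (final testing mode —
    a carrier is then excluded from its own control pools).
    """
    gene = Gene(gene)
    cfg = gene_config or DEFAULT_GENE_CONFIGS[gene]
    variants = build_fold_variants(
        reference, source_cohort, gene, sim_config, trial_policy,
        scoring_policy, matching_policy, n_composites, seed,
    )
    return _tally(variants, cfg.sd_benign, cfg.sd_pathogenic, weak_counts)


def run_fold_experiment(
    cohort_half_A: Sequence[Proband],
    cohort_half_B: Sequence[Proband],
    gene: Gene,
    sim_config: SimVariantConfig,
    trial_policy: TrialPolicy = TrialPolicy(),
    **kwargs,
) -> tuple[ConfusionCounts, list[tuple[Gene, str, int, EvaluationCall]]]:
    """One cross-validation fold: tables/pools from half A, variants from
    half B.  The halves must be disjoint."""
    ids_a = {p.proband_id for p in cohort_half_A}
    if any(p.proband_id in ids_a for p in cohort_half_B):
        raise ValueError("cohort halves must be disjoint")
    return run_simulated_variant_experiment(
        cohort_half_A, cohort_half_B, gene, sim_config, trial_policy, **kwargs
    )


# ---------------------------------------------------------------------------
# Calibration


@dataclass(frozen=True, slots=True)
class FoldOutcome:
    ppv: float
    npv: float
    counts: ConfusionCounts


@dataclass(frozen=True)
class CalibrationResult:
    gene: Gene
    sd_benign: float
    sd_pathogenic: float
    mean_ppv: float
    mean_npv: float
    min_ppv: float
    min_npv: float
    call_rate: float  # directional calls / trials
    correct_call_rate: float  # correct directional calls / trials
    fold_outcomes: tuple[FoldOutcome, ...]


def _pair_outcome(
    fold_variants: Sequence[Sequence[IncrementalVariant]],
    sd_b: float,
    sd_p: float,
    prevalence: float,
    weak_counts: bool,
):
    outcomes = []
    calls = 0
    correct = 0
    trials = 0
    for variants in fold_variants:
        counts, _ = _tally(variants, sd_b, sd_p, weak_counts)
        try:
            ppv, npv = adjusted_ppv_npv(counts, prevalence)
        except UndefinedPredictiveValueError:
            return None
        outcomes.append(FoldOutcome(ppv, npv, counts))
        calls += counts.tp + counts.fp + counts.fn + counts.tn
        correct += counts.tp + counts.tn
        trials += counts.total_pathogenic + counts.total_benign
    trials = max(trials, 1)
    return outcomes, calls / trials, correct / trials


def calibrate_sd_thresholds(
    cohort: Sequence[Proband],
    grid: CalibrationGrid = CalibrationGrid(),
    sim_config: SimVariantConfig = SimVariantConfig(n_pathogenic=1200, n_benign=4000),
    trial_policy: TrialPolicy = TrialPolicy(),
    genes: Sequence[Gene] = tuple(Gene),
    gene_configs: Mapping[Gene, GeneConfig] = DEFAULT_GENE_CONFIGS,
    scoring_policy: ScoringPolicy = ScoringPolicy(),
    matching_policy: MatchingPolicy = MatchingPolicy(),
    n_composites: Optional[int] = None,
    weak_counts: bool = True,
    n_halvings: int = 4,
    mean_floor: float = 0.9975,
    fold_floor: float = 0.996,
    seed: int = 0,
) -> dict[Gene, CalibrationResult]:
    """Grid-search the SD multipliers over four two-fold cross validations.

    Admissible pairs have across-fold mean adjusted PPV and NPV above
    ``mean_floor`` with no fold value below ``fold_floor``; among
    admissible pairs the one with the highest *correct* directional-call
    rate is selected, with ties resolved toward the larger (stricter)
    sd_pathogenic, then sd_benign.  Counting wrong calls toward the
    objective would reward shrinking the guards until errors displace
    no-calls, so only calls that agree with truth earn credit; on exact
    ties the extra strictness is free.  Raises
    :class:`CalibrationError` carrying the best near-miss when no pair
    qualifies.  Deterministic for fixed cohort, grid and seed.
    """
    cohort = list(cohort)
    fold_variants: dict[Gene, list[list[IncrementalVariant]]] = {g: [] for g in genes}
    for h in range(n_halvings):
        perm = np.random.default_rng([seed, 23, h]).permutation(len(cohort))
        half1 = [cohort[i] for i in perm[: len(cohort) // 2]]
        half2 = [cohort[i] for i in perm[len(cohort) // 2 :]]
        for d, (ref, src) in enumerate(((half1, half2), (half2, half1))):
            for gi, gene in enumerate(genes):
                variants = build_fold_variants(
                    ref, src, gene, sim_config, trial_policy,
                    scoring_policy, matching_policy, n_composites,
                    seed=int(np.random.default_rng([seed, 31, h, d, gi]).integers(1 << 31)),
                )
                fold_variants[gene].append(variants)

    results: dict[Gene, CalibrationResult] = {}
    for gene in genes:
        prevalence = gene_configs[gene].variant_pathogenic_prevalence
        best: Optional[CalibrationResult] = None
        near_miss: Optional[CalibrationResult] = None
        for sd_b, sd_p in grid.pairs():
            out = _pair_outcome(fold_variants[gene], sd_b, sd_p, prevalence, weak_counts)
            if out is None:
                continue
            outcomes, call_rate, correct_rate = out
            ppvs = [o.ppv for o in outcomes]
            npvs = [o.npv for o in outcomes]
            cand = CalibrationResult(
                gene, sd_b, sd_p,
                float(np.mean(ppvs)), float(np.mean(npvs)),
                min(ppvs), min(npvs), call_rate, correct_rate, tuple(outcomes),
            )
            admissible = (
                cand.mean_ppv > mean_floor
                and cand.mean_npv > mean_floor
                and min(cand.min_ppv, cand.min_npv) >= fold_floor
            )
            if admissible:
                key = (cand.correct_call_rate, cand.sd_pathogenic, cand.sd_benign)
                best_key = (
                    None
                    if best is None
                    else (best.correct_call_rate, best.sd_pathogenic, best.sd_benign)
                )
                if best_key is None or key > best_key:
                    best = cand
            else:
                nm_key = min(cand.mean_ppv, cand.mean_npv)
                if near_miss is None or nm_key > min(near_miss.mean_ppv, near_miss.mean_npv):
                    near_miss = cand
        if best is None:
            logger.info("calibration near-miss for %s: %r", gene.value, near_miss)
            raise CalibrationError(
                f"no admissible SD pair for {gene.value}", best_near_miss=near_miss
            )
        results[gene] = best
    return results


# ---------------------------------------------------------------------------
# True-variant trials and profiling


def true_variant_trials(
    variants: Sequence[VariantObservation],
    probands: Mapping[str, Proband],
    reference: Sequence[Proband],
    gene: Gene,
    trial_policy: TrialPolicy = TrialPolicy(),
    gene_config: Optional[GeneConfig] = None,
    scoring_policy: ScoringPolicy = ScoringPolicy(),
    matching_policy: MatchingPolicy = MatchingPolicy(),
    n_composites: Optional[int] = None,
    weak_counts: bool = True,
    seed: int = 0,
) -> tuple[ConfusionCounts, list[tuple[Gene, str, int, EvaluationCall]]]:
    """Repeated-trial evaluation of labelled true variants.

    Each variant undergoes ``trial_policy.n_trials`` independent
    incremental calls (fresh random carrier order per trial); every trial
    contributes one unit to the confusion counts.
    """
    gene = Gene(gene)
    cfg = gene_config or DEFAULT_GENE_CONFIGS[gene]
    elig_ref, _ = filter_eligible(list(reference), gene)
    table = estimate_table(elig_ref, gene, scoring_policy)
    engine = CallEngine(
        elig_ref, gene, table, scoring_policy, matching_policy, n_composites
    )
    counts = ConfusionCounts()
    details = []
    for vi, obs in enumerate(variants):
        if obs.truth_label is None:
            raise ValueError(f"variant {obs.variant_id} lacks a truth label")
        if len(obs.carrier_ids) < trial_policy.start_probands:
            raise InsufficientProbandsError(
                f"variant {obs.variant_id} has {len(obs.carrier_ids)} carriers"
            )
        for t in range(trial_policy.n_trials):
            rng = np.random.default_rng([seed, 41, vi, t])
            order = rng.permutation(len(obs.carrier_ids))
            entries = [probands[obs.carrier_ids[i]] for i in order]
            iv = IncrementalVariant(engine, entries, int(rng.integers(1 << 31)), trial_policy)
            res, used = iv.evaluate(cfg.sd_benign, cfg.sd_pathogenic)
            call = call_for_evaluation(res, weak_counts)
            counts.record(obs.truth_label, call)
            details.append((gene, obs.truth_label, used, call))
    return counts, details


class ProfileSummary(NamedTuple):
    n: int
    median: float
    deciles: tuple[float, ...]  # 10th..90th percentiles
    frac_le_10: float
    frac_le_20: float


def probands_to_call_profile(
    results: Sequence[tuple[Gene, str, int, EvaluationCall]],
) -> dict[tuple[Gene, EvaluationCall], ProfileSummary]:
    """Distribution of probands needed per successful call, by gene and
    call direction (no-call trials are not profiled)."""
    if not results:
        raise ValueError("no results to profile")
    groups: dict[tuple[Gene, EvaluationCall], list[int]] = {}
    for gene, _label, used, call in results:
        if call is EvaluationCall.NO_CALL:
            continue
        groups.setdefault((gene, call), []).append(used)
    out = {}
    for key, used in groups.items():
        arr = np.array(used, dtype=float)
        out[key] = ProfileSummary(
            n=len(arr),
            median=float(np.median(arr)),
            deciles=tuple(float(x) for x in np.percentile(arr, range(10, 100, 10))),
            frac_le_10=float(np.mean(arr <= 10)),
            frac_le_20=float(np.mean(arr <= 20)),
        )
    return out
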