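"""Six-way decision rule over the two composite-control distributions.

A variant's log history weighting score ``s`` is compared against the
positive (pathogenic-carrier) and negative (benign/no-variant)
composite-control distributions.  Let

* ``pos_99``        = 99th percentile of the positive distribution,
* ``pos_995_plus``  = 99.5th percentile + sd_benign * SD(positive),
* ``neg_05_minus``  = 0.5th percentile - sd_pathogenic * SD(negative),
* ``neg_1``         = 1st percentile of the negative distribution.

The pathogenic call requires ``s`` below both the bulk of the positive
distribution and far below the negative one; the benign call is the
mirror image.  Weak (directional but boundary-adjacent) calls are only
permitted when the two weak thresholds overlap
(``neg_05_minus <= pos_995_plus``); the standard-deviation multipliers
are the gene-specific calibrated quantities.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .cohort import GeneConfig
from .controls import ControlDistribution
from .weighting import ScoringPolicy, VariantScore

__all__ = [
    "Category",
    "EvaluationCall",
    "GeneThresholds",
    "ClassificationResult",
    "compute_thresholds",
    "classify",
    "classify_score",
    "call_for_evaluation",
]


class Category(str, enum.Enum):
    PATHOGENIC = "Pathogenic"
    WEAK_PATHOGENIC = "WeakPathogenic"
    NOT_CALLABLE = "NotCallable"
    WEAK_BENIGN = "WeakBenign"
    BENIGN = "Benign"
    INDETERMINATE = "Indeterminate"
    INSUFFICIENT_PROBANDS = "InsufficientProbands"


class EvaluationCall(str, enum.Enum):
    PATHOGENIC_CALL = "pathogenic_call"
    BENIGN_CALL = "benign_call"
    NO_CALL = "no_call"


@dataclass(frozen=True, slots=True)
class GeneThresholds:
    pos_99: float
    pos_995_plus: float
    neg_05_minus: float
    neg_1: float

    def __post_init__(self) -> None:
        for name in ("pos_99", "pos_995_plus", "neg_05_minus", "neg_1"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True, slots=True)
class ClassificationResult:
    category: Category
    log_hws: float
    thresholds: GeneThresholds
    n_used: int


def compute_thresholds(
    pos: ControlDistribution, neg: ControlDistribution, config: GeneConfig
) -> GeneThresholds:
    """Derive the four decision thresholds from the control distributions."""
    return GeneThresholds(
        pos_99=pos.percentile(99.0),
        pos_995_plus=pos.percentile(99.5) + config.sd_benign * pos.sd,
        neg_05_minus=neg.percentile(0.5) - config.sd_pathogenic * neg.sd,
        neg_1=neg.percentile(1.0),
    )


def classify_score(
    log_hws: float,
    n_used: int,
    thresholds: GeneThresholds,
    policy: ScoringPolicy = ScoringPolicy(),
) -> ClassificationResult:
    """Apply the decision table to a raw (score, proband count) pair.

    Boundary inclusivity is literal: strict inequalities gate the
    Pathogenic and Benign rows, closed intervals the weak rows, so an
    exact-boundary score lands in a weak row (when weak rows are
    admissible).  The regions partition the real line; Indeterminate is
    the residual category.
    """
    if n_used < policy.min_probands:
        return ClassificationResult(Category.INSUFFICIENT_PROBANDS, log_hws, thresholds, n_used)
    s = log_hws
    t = thresholds
    weak_ok = t.neg_05_minus <= t.pos_995_plus
    if s < t.pos_99 and s < t.neg_05_minus:
        cat = Category.PATHOGENIC
    elif t.pos_99 <= s <= t.pos_995_plus and s < t.neg_05_minus and weak_ok:
        cat = Category.WEAK_PATHOGENIC
    elif s > t.pos_995_plus and s < t.neg_05_minus:
        cat = Category.NOT_CALLABLE
    elif s > t.pos_995_plus and t.neg_05_minus <= s <= t.neg_1 and weak_ok:
        cat = Category.WEAK_BENIGN
    elif s > t.pos_995_plus and s > t.neg_1:
        cat = Category.BENIGN
    else:
        cat = Category.INDETERMINATE
    return ClassificationResult(cat, s, thresholds, n_used)


def classify(
    score: VariantScore,
    thresholds: GeneThresholds,
    policy: ScoringPolicy = ScoringPolicy(),
) -> ClassificationResult:
    return classify_score(score.log_hws, score.n_used, thresholds, policy)


#: Categories that terminate the incremental-call protocol.
DIRECTIONAL_CATEGORIES = frozenset(
    {Category.PATHOGENIC, Category.WEAK_PATHOGENIC, Category.WEAK_BENIGN, Category.BENIGN}
)


def call_for_evaluation(
    result: ClassificationResult, weak_counts: bool = True
) -> EvaluationCall:
    """Collapse a category to the three-way call counted in PPV/NPV.

    Weak categories map to their direction when ``weak_counts`` is true,
    otherwise to no-call; NotCallable, Indeterminate and
    InsufficientProbands are never counted.
    """
    cat = result.category
    if cat is Category.PATHOGENIC:
        return EvaluationCall.PATHOGENIC_CALL
    if cat is Category.BENIGN:
        return EvaluationCall.BENIGN_CALL
    if cat is Category.WEAK_PATHOGENIC:
        return EvaluationCall.PATHOGENIC_CALL if weak_counts else EvaluationCall.NO_CALL
    if cat is Category.WEAK_BENIGN:
        return EvaluationCall.BENIGN_CALL if weak_counts else EvaluationCall.NO_CALL
    return EvaluationCall.NO_CALL
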