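# Methods

## The model

`historyweight` classifies variants in the mismatch-repair genes *MLH1*,
*MSH2* and *MSH6* as pathogenic or benign from the aggregated personal
and family cancer histories of the probands who carry them.  The premise
is ascertainment-driven: pathogenic Lynch-syndrome variants are found
preferentially in people tested *because of* strong colorectal /
endometrial / ovarian cancer histories, while a benign variant's
carriers look like the testing population at large.

For each proband the probability `q` of carrying a pathogenic mutation
in the gene, conditional on a discretized history, is estimated from a
reference cohort and stored in a gene-specific conditional probability
table.  Against the cohort prior `π`, the proband's likelihood ratio is
the posterior-to-prior odds ratio of *not* carrying a mutation,

    LR = [(1 − q)/q] / [(1 − π)/π],

so history-enriched probands contribute LR < 1.  A variant's history
weighting score is the product of its carriers' LRs — the log score is
the sum — over at most the 100 most recent carriers by test date (ties
broken by proband id so selection is deterministic).  "Assuming
independence" is taken literally: no within-family correction is applied
at scoring time; unknown relatedness is stress-tested instead by the
simulated-variant duplication mechanism (below).

The score is judged against two null distributions built per variant.
For every carrier, a pool of ≥ 100 control probands is accumulated in
precedence order — ethnicity-matched within ±180 days of the carrier's
test date, then ethnicity-unmatched in the same window, then both again
in each successive ±180-day expansion (time-of-testing ascertainment
bias dominates ethnicity bias, so the window takes precedence; probands
with unspecified ancestry use unmatched candidates from the start).
Positive controls carry known pathogenic mutations in the gene; negative
controls carry benign or no variants in every Lynch gene.  A *composite
control variant* substitutes one uniformly drawn control per carrier and
sums their log LRs; 10,000 replicates (1,000 in the scaled experiments)
form each empirical distribution.  Controls are unique within a pool but
re-drawn freely across replicates.  A carrier is never a member of its
own pool.

Classification uses four thresholds: the 99th percentile of the positive
ECDF; the 99.5th percentile plus `sd_benign` standard deviations of the
positive ECDF; the 0.5th percentile minus `sd_pathogenic` standard
deviations of the negative ECDF; and the 1st percentile of the negative
ECDF.  Pathogenic requires the score strictly below the first and third;
Benign strictly above the second and fourth; the intermediate rows
(Weak Pathogenic, Not Callable, Weak Benign, Indeterminate) fill the
rest of the line, with weak rows admitted only when the two SD-adjusted
thresholds overlap (`neg_05_minus ≤ pos_995_plus`).  Exact-boundary
scores land in weak rows.  At least five carrier observations are
required for any call.  By default weak calls count toward their
direction in the evaluation tallies (configurable via `weak_counts`).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `ScoringPolicy.max_probands` | 100 | recency cap on carriers scored |
| `ScoringPolicy.min_probands` | 5 | minimum observations for any call |
| `ScoringPolicy.pseudocount` | 0.5 | symmetric smoothing of table cells |
| `MatchingPolicy.window_halfwidth_days` | 180 | matching half-window (days) |
| `MatchingPolicy.min_controls_per_proband` | 100 | pool size target per carrier |
| `MatchingPolicy.n_composites` | 10,000 | composite replicates per ECDF |
| `GeneConfig.sd_benign` | 0.7 / 0.9 / 1.0 | SD multiplier, benign direction (MLH1/MSH2/MSH6) |
| `GeneConfig.sd_pathogenic` | 2.2 / 2.3 / 2.2 | SD multiplier, pathogenic direction |
| `GeneConfig.variant_pathogenic_prevalence` | 0.242 / 0.168 / 0.129 | prior that a variant in the gene is pathogenic |
| `TrialPolicy.start_probands` | 5 | incremental protocol start |
| `TrialPolicy.growth_factor` | 1.2 | per-round growth (ceiling) |
| `SimVariantConfig.duplication_probability` | 0.05 | relatedness emulation |

Cell smoothing is symmetric, `q = (carriers + c)/(total + 2c)` with
`c = 0.5`: it guarantees finite log LRs in sparse cells; cells never
observed fall back to `π` exactly (LR = 1, i.e. no evidence).

The history discretization is per scored site (colorectal, endometrial,
ovarian): personal status unaffected vs. earliest-diagnosis age bin in
{<35, 35–49, 50–64, ≥65}; affected-relative count capped at 3 crossed
with the earliest relative onset bin; plus the proband's current-age
bin.  Any fixed, total, finite discretization preserves the algorithm's
logic; this one balances resolution against estimability from cohorts of
a few tens of thousands.  Ethnicity is deliberately *not* conditioned on
in the tables — it is used only for control matching.  Unrelated cancers
and rare Lynch-associated cancers in relatives are recorded but never
scored; a rare Lynch-associated cancer in the proband's own history
excludes the proband (too little reference data), as do missing
histories and pathogenic/VUS findings in a Lynch gene other than the one
under analysis.

## Prevalence-adjusted predictive values

Raw per-class call rates (`r_tp = tp/total_pathogenic`,
`r_fp = fp/total_benign`, …) are reweighted by the prior probability `p`
that a variant in the gene is pathogenic:

    PPV = r_tp·p / (r_tp·p + r_fp·(1−p))
    NPV = r_tn·(1−p) / (r_tn·(1−p) + r_fn·p),   NPV = 1 when fn = 0.

Only definitive (and, by default, weak) pathogenic/benign calls enter
the tallies; no-calls are excluded.  `adjusted_ppv_npv` reproduces all
sixteen PPV/NPV values printable from published Lynch-HWA confusion
tables to four decimal places (see `tests/test_acceptance.py`).

## Threshold calibration

The SD multipliers are the only fitted quantities.  They are selected by
four independent random halvings of the cohort, each half serving once
as table-builder and once as variant source (8 folds).  For every grid
pair, prevalence-adjusted PPV/NPV are computed on each fold; a pair is
admissible when the across-fold means both exceed 0.9975 and no fold
value falls below 0.996.  Among admissible pairs the one with the
highest **correct** directional-call rate is selected, ties resolved
toward the larger (stricter) `sd_pathogenic`, then `sd_benign`.  All
admissible pairs already meet the error bar, so the remaining currency
is call volume — but counted over *correct* calls only.  Maximizing the
raw call rate instead is perverse: an erroneous directional call counts
the same as a correct one, so the objective rewards shrinking a guard
until errors displace no-calls while the fold floors are still
(barely) met; empirically this selects the smallest `sd_benign` on the
grid and inflates false-negative calls severalfold for the weaker-
separating genes.  Because fold error counts are small integers, exact
ties in the correct-call rate are common, and the stricter pair is then
free insurance.  The default grid spans 0.5–1.2 × 1.8–4.0 and contains
the clinically deployed values (0.7–1.0, 2.2–2.3).

Two design choices in the fold construction deserve note:

* **Control pools come from the variant-source half**, scored under the
  *other* half's table.  Drawing controls from the table-building half
  instead creates a train/test asymmetry — held-out carriers fall into
  table cells never seen in training and have their log LRs shrunk
  toward zero, while in-sample controls keep fully signed log LRs — that
  systematically pushes genuinely pathogenic variants toward benign
  calls.  Keeping carriers and controls in the same half means both
  sides of the comparison are out-of-sample with respect to the table.
* **Simulated-variant sources.**  The clinical pipeline sampled carriers
  from observed true variants; the synthetic stand-in partitions each
  half's carrier stratum into disjoint planted "true variants" of 2–4
  carriers (rare pathogenic variants) and the non-carrier stratum into
  benign sources of 20–40 carriers (common benign variants, capped at 60
  sources).  A simulated variant draws one random carrier per source;
  each carrier after the first is duplicated with probability 0.05 and
  contributes its LR once per appearance.  Small pathogenic sources
  matter: the log score grows roughly linearly in the carrier count
  while the SD-guarded threshold grows like √k, so the weakly separating
  gene (MSH6) needs ~40+ carriers available before its pathogenic calls
  resolve; source size bounds the carriers a simulated variant can reach.

Scaled problem sizes: calibration uses 1,200 pathogenic and 4,000 benign
simulated variants per fold and gene.  The benign count follows a
resolution argument: at MSH6's prevalence (0.129) the 0.996 fold floor
corresponds to a false-positive call rate of ≈ 5×10⁻⁴, so the fold must
be large enough that the floor sits at ≥ 2 events rather than letting a
single stochastic false positive condemn a fold.  The pathogenic side
faces a much looser floor (≈ 1.3×10⁻² false-negative rate) and can be
smaller.  The final evaluation uses 2,550 pathogenic and 5,050 benign
simulated variants per gene (the published design scaled tenfold down,
mix preserved) with tables and pools from the entire cohort.

## The synthetic cohort generator

The generator emulates the *statistical structure* the algorithm relies
on, not oncologic reality.  Per site, disease is a piecewise-linear
cumulative risk from age 25 to a terminal risk at 70 (flat afterwards),
sampled by inverse CDF; carriers of each gene get gene-specific curves
(colorectal 0.55/0.52/0.20, endometrial 0.30/0.30/0.24, ovarian
0.08/0.10/0.04 for MLH1/MSH2/MSH6 — the clinical ordering MLH1 ≈ MSH2 >
MSH6), non-carriers the population baseline (0.05/0.026/0.013).  Risks
are cohort-averaged; proband sex is not modelled.  Affected-relative
counts are Poisson (mean 1.4 for carriers vs 0.35 for non-carriers);
a carrier's relative inherits the mutation with probability 0.5
(first-degree) or 0.25 (second-degree) and then draws from the carrier
curves.  Ethnicity is drawn from a 7-category distribution including
"unspecified"; test dates are uniform over 2012–2015; carrier fractions
are 2.0 %/1.8 %/1.5 % — a high-risk referral population.  The generator
injects the records the eligibility filter must catch (2 % missing
histories, 1 % personal rare-Lynch cancers, 1 % extra pathogenic/VUS
findings), plus VUS (4 %) and benign-only (12 %) findings, unrelated
cancers (8 %), and cryptic relatedness (1 % of probands share a family
id and the family-history record of an earlier proband, and inherit a
partner carrier's mutation with probability 0.5).  The algorithm never
sees family ids; they exist so relatedness stress tests have ground
truth.

What passing tests on this generator do **not** show: robustness to real
intake-form noise (free-text histories, reporting biases, secular trends
in ascertainment), to mis-specified penetrance, or to cohorts pooled
across laboratories with heterogeneous documentation practices.  The
directional contrasts (carrier vs non-carrier history enrichment,
MLH1/MSH2 vs MSH6 separability) are assumptions stated here, not
reconstructions of any clinical dataset.

## Numerical choices

* Quantiles: linear interpolation between order statistics with plotting
  position (k−1)/(n−1) (`numpy.quantile`, method="linear"); p=0/100 are
  the minimum/maximum.  Any consistent convention works — calibration
  absorbs the difference.
* ECDF dispersion: sample standard deviation (n−1) of the composite
  scores; 0 for a single replicate.
* Composite replicates grow incrementally with the carrier prefix during
  the incremental protocol (each replicate keeps a running sum; newly
  added carriers contribute fresh uniform pool draws keyed by
  (variant seed, iteration, side)).  Every iteration's distribution is
  exactly one independent pool draw per carrier; randomness is
  independent of evaluation order, so lazy calibration replay is
  deterministic.
* Growth schedule: `ceil(count × 1.2)` with a 10⁻⁹ guard against binary
  round-off, clipped at the available carriers: 5, 6, 8, 10, 12, 15, 18,
  22, 27, 33, …
* Degenerate inputs: empty cohorts, all-carrier/all-non-carrier tables,
  `q` or `π` at {0,1}, empty pools and exhausted strata raise typed
  errors (`historyweight.errors`); pool exhaustion below the 100-control
  minimum is logged and tolerated (the pool proceeds with what exists).
* All randomness flows from a master seed through named substreams
  (`numpy` `default_rng` seeded with structured integer lists), so
  cohort generation, variant construction, composites and trials are
  individually reproducible.

## Known limitations

* A proband may contribute to more than one variant's analysis; no
  cross-variant exclusivity is enforced.
* Low-penetrance variants are out of reach by construction: their
  carriers' histories sit between the two nulls and yield persistent
  Not Callable / Indeterminate outcomes.
* The binning scheme is fixed at import time; swapping it requires
  re-estimating tables (the persisted table format records the key
  fields, counts and smoothed probabilities so scoring is reproducible
  across runs).
* PMS2/EPCAM are not modelled, and no pedigree structure beyond summary
  relative records exists anywhere in the system.
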