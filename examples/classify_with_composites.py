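"""Classify a pathogenic and a benign variant with the full two-hypothesis
test.

For each carrier of a variant, matched control pools (ethnicity, +/-180
day test-date windows) are drawn from pathogenic-mutation carriers
(positive controls) and from probands with benign or no variants
(negative controls).  Summing one random control log LR per carrier
n_composites times gives the two composite null distributions; the variant's score
is compared to their percentile/SD thresholds via the six-way decision
table.
"""

from historyweight import (
    DEFAULT_GENE_CONFIGS,
    Gene,
    MatchingPolicy,
    SimCohortConfig,
    build_composites,
    call_for_evaluation,
    classify,
    compute_thresholds,
    estimate_table,
    filter_eligible,
    generate_cohort,
    history_weighting_score,
    plant_variant,
    select_matched_controls,
)

probands, truth = generate_cohort(SimCohortConfig(n_probands=8000, seed=42))
gene = Gene.MSH2
eligible, _ = filter_eligible(probands, gene)
table = estimate_table(eligible, gene)
by_id = {p.proband_id: p for p in probands}
policy = MatchingPolicy(n_composites=2000)

for label in ("pathogenic", "benign"):
    variant = plant_variant(probands, truth, gene, label, n_carriers=10, seed=11)
    score = history_weighting_score(variant, by_id, table)
    carriers = [by_id[cid] for cid in score.proband_ids_used]
    pos_pools = [select_matched_controls(p, eligible, "positive", gene, policy) for p in carriers]
    neg_pools = [select_matched_controls(p, eligible, "negative", gene, policy) for p in carriers]
    pos = build_composites(pos_pools, by_id, table, policy, seed=1)
    neg = build_composites(neg_pools, by_id, table, policy, seed=2)
    thresholds = compute_thresholds(pos, neg, DEFAULT_GENE_CONFIGS[gene])
    result = classify(score, thresholds)
    call = call_for_evaluation(result)
    print(f"{label:>10} variant: log HWS = {score.log_hws:+8.2f}  "
          f"pos[P99={thresholds.pos_99:+.2f}, P99.5+{DEFAULT_GENE_CONFIGS[gene].sd_benign}SD={thresholds.pos_995_plus:+.2f}]  "
          f"neg[P0.5-{DEFAULT_GENE_CONFIGS[gene].sd_pathogenic}SD={thresholds.neg_05_minus:+.2f}, P1={thresholds.neg_1:+.2f}]")
    print(f"{'':>10}          -> category {result.category.value}, evaluation call {call.value}")
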