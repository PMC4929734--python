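"""Watch the incremental-call protocol grow a variant's carrier set.

Starts from 5 randomly selected carriers and attempts a call; on
NotCallable/Indeterminate the carrier count grows by 20 % (ceiling,
previous selections retained) until a directional call succeeds or the
carriers run out.  Weakly separating variants therefore consume more
probands - the basis of the probands-to-call profiling.
"""

from historyweight import (
    DEFAULT_GENE_CONFIGS,
    Gene,
    SimCohortConfig,
    TrialPolicy,
    estimate_table,
    filter_eligible,
    generate_cohort,
    plant_variant,
    run_incremental_call,
)

probands, truth = generate_cohort(SimCohortConfig(n_probands=8000, seed=42))
gene = Gene.MSH6
eligible, _ = filter_eligible(probands, gene)
table = estimate_table(eligible, gene)
by_id = {p.proband_id: p for p in eligible}

variant = plant_variant(probands, truth, gene, "pathogenic", n_carriers=60, seed=3)
result, probands_used = run_incremental_call(
    variant, by_id, eligible, table, DEFAULT_GENE_CONFIGS[gene],
    TrialPolicy(), n_composites=1000, seed=9,
)
print(f"{gene.value} pathogenic variant with {len(variant.carrier_ids)} carriers available")
print(f"final category: {result.category.value} after {probands_used} probands")
print(f"log HWS at stop: {result.log_hws:+.2f}; pathogenic-call threshold "
      f"(0.5th pct - {DEFAULT_GENE_CONFIGS[gene].sd_pathogenic} SD of negative composites): "
      f"{result.thresholds.neg_05_minus:+.2f}")
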