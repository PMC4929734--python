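"""Calibrate the SD threshold multipliers on a small synthetic cohort.

Runs the four two-fold cross-validation grid search at reduced scale
(one gene, 100 pathogenic / 300 benign simulated variants per fold) and
prints the selected pair with its fold-level predictive values.  A pair
is admissible when the across-fold mean adjusted PPV and NPV both exceed
0.9975 and no fold falls below 0.996; among admissible pairs the one
calling the most variants wins.
"""

from historyweight import (
    Gene,
    SimCohortConfig,
    SimVariantConfig,
    calibrate_sd_thresholds,
    generate_cohort,
)

probands, _ = generate_cohort(SimCohortConfig(n_probands=10_000, seed=42))
results = calibrate_sd_thresholds(
    probands,
    sim_config=SimVariantConfig(n_pathogenic=100, n_benign=300),
    genes=[Gene.MLH1],
    n_composites=500,
    seed=5,
)
r = results[Gene.MLH1]
print(f"selected for MLH1: sd_benign={r.sd_benign}, sd_pathogenic={r.sd_pathogenic}")
print(f"across 8 folds: mean PPV={r.mean_ppv:.4f}, mean NPV={r.mean_npv:.4f}, "
      f"fold minima PPV={r.min_ppv:.4f}/NPV={r.min_npv:.4f}, call rate={r.call_rate:.3f}")
for i, o in enumerate(r.fold_outcomes):
    c = o.counts
    print(f"  fold {i}: PPV={o.ppv:.4f} NPV={o.npv:.4f} "
          f"(tp={c.tp} fp={c.fp} fn={c.fn} tn={c.tn} no-call={c.nocall_pathogenic}+{c.nocall_benign})")
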