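"""Simulated-variant construction, the incremental-call protocol,
prevalence-adjusted predictive values, and profiling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from historyweight import (
    CalibrationGrid,
    Category,
    ConfusionCounts,
    EvaluationCall,
    Gene,
    GeneConfig,
    SimVariantConfig,
    TrialPolicy,
    adjusted_ppv_npv,
    filter_eligible,
    growth_sequence,
    make_simulated_variant,
    plant_disjoint_variants,
    probands_to_call_profile,
    run_fold_experiment,
    run_incremental_call,
    true_variant_trials,
)
from historyweight.errors import (
    StratumExhaustedError,
    UndefinedPredictiveValueError,
)
from historyweight.experiments import build_fold_variants, _tally
from historyweight.weighting import estimate_table
from historyweight.classify import call_for_evaluation


class TestGrowthSequence:
    def test_ceiling_recurrence_from_five(self):
        seq = growth_sequence(5, 1.2, 1000)
        assert seq[:10] == [5, 6, 8, 10, 12, 15, 18, 22, 27, 33]

    def test_clipped_at_available_carriers(self):
        assert growth_sequence(5, 1.2, 9) == [5, 6, 8, 9]
        assert growth_sequence(5, 1.2, 5) == [5]

    def test_empty_below_start(self):
        assert growth_sequence(5, 1.2, 4) == []


class TestMakeSimulatedVariant:
    def _sources(self, small_cohort, gene=Gene.MLH1, label="pathogenic", sizes=(3,) * 30):
        probands, truth = small_cohort
        return plant_disjoint_variants(probands, truth, gene, label, list(sizes), seed=5)

    def test_single_source_has_no_duplicates(self, small_cohort):
        sources = self._sources(small_cohort)
        cfg = SimVariantConfig(seed=3)
        obs = make_simulated_variant(sources, "pathogenic", 1, cfg)
        assert len(obs.carrier_ids) == 1

    def test_duplication_probability_default(self):
        assert SimVariantConfig().duplication_probability == 0.05

    def test_duplicate_rate_matches_binomial_oracle(self, small_cohort):
        """Duplicates across repeated builds follow Binomial(n-1, 0.05)."""
        sources = self._sources(small_cohort, sizes=(3,) * 25)
        cfg = SimVariantConfig()
        n = 21
        rng = np.random.default_rng(99)
        builds = 4000
        dup_counts = [
            sum(make_simulated_variant(sources, "pathogenic", n, cfg, rng).duplicate_flags)
            for _ in range(builds)
        ]
        p = cfg.duplication_probability
        expected = (n - 1) * p
        se = math.sqrt((n - 1) * p * (1 - p) / builds)
        assert abs(np.mean(dup_counts) - expected) <= 3 * se

    def test_carriers_come_one_per_source(self, small_cohort):
        sources = self._sources(small_cohort)
        cfg = SimVariantConfig(seed=8)
        obs = make_simulated_variant(sources, "pathogenic", 10, cfg)
        source_of = {
            cid: s.variant_id for s in sources for cid in s.carrier_ids
        }
        used_sources = [source_of[cid] for cid, dup in zip(obs.carrier_ids, obs.duplicate_flags) if not dup]
        assert len(used_sources) == len(set(used_sources)) == 10

    def test_exhaustion_error(self, small_cohort):
        sources = self._sources(small_cohort, sizes=(3,) * 5)
        with pytest.raises(StratumExhaustedError):
            make_simulated_variant(sources, "pathogenic", 6, SimVariantConfig())


class TestAdjustedPpvNpv:
    def test_fp_zero_gives_unit_ppv_for_any_prevalence(self):
        counts = ConfusionCounts(tp=100, fp=0, fn=3, tn=200, nocall_pathogenic=7, nocall_benign=2)
        for p in (0.05, 0.242, 0.9):
            ppv, _ = adjusted_ppv_npv(counts, p)
            assert ppv == 1.0

    def test_fn_zero_gives_unit_npv(self):
        counts = ConfusionCounts(tp=10, fp=1, fn=0, tn=50)
        assert adjusted_ppv_npv(counts, 0.242)[1] == 1.0

    def test_reduces_to_raw_ppv_at_the_simulated_mix(self):
        counts = ConfusionCounts(tp=240, fp=6, fn=4, tn=480, nocall_pathogenic=6, nocall_benign=14)
        p = counts.total_pathogenic / (counts.total_pathogenic + counts.total_benign)
        ppv, _ = adjusted_ppv_npv(counts, p)
        assert ppv == pytest.approx(counts.tp / (counts.tp + counts.fp))

    def test_undefined_when_no_calls_on_one_side(self):
        with pytest.raises(UndefinedPredictiveValueError):
            adjusted_ppv_npv(
                ConfusionCounts(nocall_pathogenic=10, nocall_benign=10), 0.2
            )

    @given(
        st.integers(90, 100), st.integers(0, 5), st.integers(1, 5), st.integers(90, 100),
        st.floats(0.05, 0.45), st.floats(0.05, 0.45),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_prevalence(self, tp, fp, fn, tn, p1, p2):
        counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        lo, hi = sorted((p1, p2))
        ppv_lo, npv_lo = adjusted_ppv_npv(counts, lo)
        ppv_hi, npv_hi = adjusted_ppv_npv(counts, hi)
        assert ppv_lo <= ppv_hi + 1e-12
        assert npv_lo >= npv_hi - 1e-12

    def test_conservation_identities(self):
        counts = ConfusionCounts(tp=7, fp=2, fn=1, tn=11, nocall_pathogenic=2, nocall_benign=3)
        assert counts.tp + counts.fn + counts.nocall_pathogenic == counts.total_pathogenic
        assert counts.fp + counts.tn + counts.nocall_benign == counts.total_benign


@pytest.fixture(scope="module")
def fold_setup(small_cohort):
    """One small fold: engine + simulated variants, reused across tests."""
    probands, _ = small_cohort
    half_a, half_b = probands[:3000], probands[3000:]
    variants = build_fold_variants(
        half_a, half_b, Gene.MLH1,
        SimVariantConfig(n_pathogenic=60, n_benign=120),
        TrialPolicy(), n_composites=400, seed=21,
    )
    return half_a, half_b, variants


class TestIncrementalCall:
    def test_vectorized_tally_matches_scalar_evaluation(self, fold_setup):
        _, _, variants = fold_setup
        counts, details = _tally(variants, 0.7, 2.2, True)
        scalar = ConfusionCounts()
        for iv, det in zip(variants, details):
            res, used = iv.evaluate(0.7, 2.2)
            call = call_for_evaluation(res, True)
            scalar.record(iv.truth_label, call)
            assert (used, call) == (det[2], det[3])
        assert scalar == counts

    def test_conservation_identities_after_experiment(self, fold_setup):
        _, _, variants = fold_setup
        counts, details = _tally(variants, 0.7, 2.2, True)
        assert counts.total_pathogenic == 60
        assert counts.total_benign == 120
        assert len(details) == 180

    def test_variant_clearing_thresholds_at_start_stops_at_start(self, small_cohort, small_truth):
        probands, truth = small_cohort
        gene = Gene.MLH1
        eligible, _ = filter_eligible(probands, gene)
        by_id = {p.proband_id: p for p in eligible}
        from historyweight import plant_variant

        obs = plant_variant(probands, truth, gene, "benign", 40, seed=31)
        table = estimate_table(eligible, gene)
        result, used = run_incremental_call(
            obs, by_id, eligible, table, GeneConfig(gene, 0.02, 0.242, 0.7, 2.2),
            TrialPolicy(), n_composites=400, seed=5,
        )
        # a typical benign variant calls immediately at the starting count
        if result.category in (Category.BENIGN, Category.WEAK_BENIGN):
            assert used == TrialPolicy().start_probands

    def test_fewer_carriers_than_start_is_insufficient(self, small_cohort):
        probands, truth = small_cohort
        gene = Gene.MLH1
        eligible, _ = filter_eligible(probands, gene)
        by_id = {p.proband_id: p for p in eligible}
        from historyweight import plant_variant

        obs = plant_variant(probands, truth, gene, "benign", 4, seed=32)
        table = estimate_table(eligible, gene)
        result, used = run_incremental_call(
            obs, by_id, eligible, table, GeneConfig(gene, 0.02, 0.242, 0.7, 2.2),
            TrialPolicy(), n_composites=400, seed=5,
        )
        assert result.category is Category.INSUFFICIENT_PROBANDS
        assert used == 4

    def test_directional_separation_of_composite_medians(self, fold_setup):
        """Positive (pathogenic-carrier) composite medians sit left of
        negative composite medians for the same carriers."""
        _, _, variants = fold_setup
        checked = 0
        for iv in variants[:10]:
            st0 = iv.stat(0)
            pos_med = np.median(
                # reconstruct both composite sets the way the engine does
                sum(iv.engine.pool_for(p, "positive")[
                    np.random.default_rng([iv.base_seed, 0, 0]).integers(
                        0, len(iv.engine.pool_for(p, "positive")), 400)
                ] for p in iv.entries[:5])
            )
            neg_med = np.median(
                sum(iv.engine.pool_for(p, "negative")[
                    np.random.default_rng([iv.base_seed, 0, 1]).integers(
                        0, len(iv.engine.pool_for(p, "negative")), 400)
                ] for p in iv.entries[:5])
            )
            assert pos_med < neg_med
            checked += 1
        assert checked == 10

    def test_fold_experiment_conservation_and_accuracy(self, small_cohort):
        probands, _ = small_cohort
        counts, details = run_fold_experiment(
            probands[:3000], probands[3000:], Gene.MLH1,
            SimVariantConfig(n_pathogenic=40, n_benign=80),
            TrialPolicy(), n_composites=400, seed=43,
        )
        assert counts.total_pathogenic == 40 and counts.total_benign == 80
        # directional calls overwhelmingly agree with truth at this scale
        assert counts.fn + counts.fp <= 2

    def test_fold_halves_must_be_disjoint(self, small_cohort):
        probands, _ = small_cohort
        with pytest.raises(ValueError):
            run_fold_experiment(
                probands[:3000], probands[2999:4000], Gene.MLH1,
                SimVariantConfig(n_pathogenic=5, n_benign=5), TrialPolicy(),
            )

    def test_zero_variants_give_all_zero_counts(self, small_cohort):
        probands, _ = small_cohort
        counts, details = run_fold_experiment(
            probands[:3000], probands[3000:], Gene.MLH1,
            SimVariantConfig(n_pathogenic=0, n_benign=0), TrialPolicy(),
            n_composites=200, seed=1,
        )
        assert counts == ConfusionCounts()
        assert details == []


class TestTrueVariantTrials:
    def test_trial_counts_and_determinism(self, small_cohort):
        probands, truth = small_cohort
        gene = Gene.MLH1
        variants = plant_disjoint_variants(probands, truth, gene, "benign", [12, 12], seed=51)
        by_id = {p.proband_id: p for p in probands}
        policy = TrialPolicy(n_trials=10)
        runs = [
            true_variant_trials(
                variants, by_id, probands, gene, policy,
                n_composites=300, seed=61,
            )
            for _ in range(2)
        ]
        counts, details = runs[0]
        assert counts.total_benign == 20 and counts.total_pathogenic == 0
        assert len(details) == 20
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]


class TestProfile:
    def test_all_calls_at_start_count(self):
        rows = [(Gene.MLH1, "benign", 5, EvaluationCall.BENIGN_CALL)] * 8
        profile = probands_to_call_profile(rows)
        summary = profile[(Gene.MLH1, EvaluationCall.BENIGN_CALL)]
        assert summary.median == 5 and summary.frac_le_10 == 1.0 and summary.n == 8

    def test_mixture_matches_hand_tally(self):
        rows = (
            [(Gene.MSH6, "pathogenic", 5, EvaluationCall.PATHOGENIC_CALL)] * 3
            + [(Gene.MSH6, "pathogenic", 22, EvaluationCall.PATHOGENIC_CALL)] * 2
            + [(Gene.MSH6, "pathogenic", 8, EvaluationCall.NO_CALL)] * 4
        )
        profile = probands_to_call_profile(rows)
        summary = profile[(Gene.MSH6, EvaluationCall.PATHOGENIC_CALL)]
        assert summary.n == 5
        assert summary.median == 5
        assert summary.frac_le_10 == pytest.approx(3 / 5)
        assert summary.frac_le_20 == pytest.approx(3 / 5)
        assert (Gene.MSH6, EvaluationCall.NO_CALL) not in profile

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            probands_to_call_profile([])


class TestCalibrationPlumbing:
    def test_default_grid_contains_clinical_values(self):
        grid = CalibrationGrid()
        assert {0.7, 0.9, 1.0} <= set(grid.sd_benign_values)
        assert {2.2, 2.3} <= set(grid.sd_pathogenic_values)

    def test_admissibility_on_hand_written_fold_table(self):
        """The admissibility rule applied to an 8-row fold table by hand:
        mean >0.9975 on both, fold minimum >=0.996."""
        ppvs = [1.0, 1.0, 0.9987, 1.0, 0.9962, 1.0, 1.0, 1.0]
        npvs = [1.0] * 8
        mean_ok = np.mean(ppvs) > 0.9975 and np.mean(npvs) > 0.9975
        min_ok = min(min(ppvs), min(npvs)) >= 0.996
        assert mean_ok and min_ok
        # degrade one fold below the floor -> inadmissible
        ppvs[4] = 0.9938
        assert not (min(min(ppvs), min(npvs)) >= 0.996)
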