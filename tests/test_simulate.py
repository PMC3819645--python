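"""Synthetic methylome/expression generators and truth-based recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from dmrscan.io import pair_methylomes
from dmrscan.qc import conversion_rate, ratio_histogram
from dmrscan.simulate import (
    DmrPlan,
    DmrPlacementError,
    SyntheticSpec,
    SyntheticTruth,
    evaluate_dmr_recovery,
    simulate_expression,
    simulate_methylomes,
    simulate_segmentation,
)
from dmrscan.expression import rank_sum_test


def _small_spec(**kwargs):
    defaults = dict(
        chrom_sizes={"chr1": 500_000},
        dmr_plan=DmrPlan(n_dmrs=5),
        control_sites=200,
        noncpg_sites=200,
        seed=1,
    )
    defaults.update(kwargs)
    return SyntheticSpec(**defaults)


class TestSimulateMethylomes:
    def test_same_seed_identical_tables(self):
        a_young, a_old, a_truth = simulate_methylomes(_small_spec())
        b_young, b_old, b_truth = simulate_methylomes(_small_spec())
        pd.testing.assert_frame_equal(a_young.sites, b_young.sites)
        pd.testing.assert_frame_equal(a_old.sites, b_old.sites)
        pd.testing.assert_frame_equal(a_truth.dmrs, b_truth.dmrs)

    def test_different_seed_differs(self):
        a_young, _, _ = simulate_methylomes(_small_spec())
        b_young, _, _ = simulate_methylomes(_small_spec(seed=2))
        assert not a_young.sites.equals(b_young.sites)

    def test_zero_dmrs_shares_generating_ratios(self):
        spec = _small_spec(dmr_plan=DmrPlan(n_dmrs=0))
        _, _, truth = simulate_methylomes(spec)
        assert truth.dmrs.empty
        np.testing.assert_array_equal(
            truth.true_ratios["ratio_young"], truth.true_ratios["ratio_old"]
        )

    def test_truth_dmrs_within_bounds_with_min_cpgs(self):
        _, _, truth = simulate_methylomes(_small_spec())
        plan = truth.spec.dmr_plan
        assert (truth.dmrs["start"] >= 0).all()
        assert (truth.dmrs["end"] <= truth.spec.chrom_sizes["chr1"]).all()
        assert (truth.dmrs["n_cpgs"] >= plan.min_cpgs).all()
        assert ((truth.dmrs["end"] - truth.dmrs["start"]) == plan.width).all()

    def test_mixture_weights_recovered_on_true_ratios(self):
        # 10-Mb chromosome at 100-bp spacing -> ~100k CpGs
        spec = _small_spec(
            chrom_sizes={"chr1": 10_000_000}, dmr_plan=DmrPlan(n_dmrs=0)
        )
        _, _, truth = simulate_methylomes(spec)
        assert len(truth.true_ratios) >= 90_000
        hist = ratio_histogram(truth.true_ratios["ratio_young"].to_numpy())
        assert hist.frac_unmethylated == pytest.approx(0.10, abs=0.01)
        assert hist.frac_partial == pytest.approx(0.40, abs=0.01)
        assert hist.frac_full == pytest.approx(0.50, abs=0.01)

    def test_observed_ratios_converge_at_high_coverage(self):
        spec = _small_spec(
            chrom_sizes={"chr1": 200_000},
            coverage_young=1000,
            coverage_old=1000,
            dmr_plan=DmrPlan(n_dmrs=0),
            control_sites=0,
            noncpg_sites=0,
        )
        young, _, truth = simulate_methylomes(spec)
        plus = young.sites[
            (young.sites["strand"] == "+") & (young.sites["context"] == "CG")
        ].set_index("pos")
        truth_map = truth.true_ratios.set_index("pos")["ratio_young"]
        mae = (plus["ratio"] - truth_map).abs().mean()
        assert mae < 0.02

    def test_conversion_rate_recovered(self):
        spec = _small_spec(control_sites=2000, conversion_error_young=0.0016)
        young, _, _ = simulate_methylomes(spec)
        rate = conversion_rate(young.on_contig("chrM"))
        assert rate == pytest.approx(1 - 0.0016, abs=0.001)

    def test_both_strands_emitted(self):
        young, _, _ = simulate_methylomes(_small_spec())
        cg = young.sites[young.sites["context"] == "CG"]
        cg = cg[cg["chrom"] == "chr1"]
        assert set(cg["strand"]) == {"+", "-"}
        assert (cg["strand"] == "+").sum() == (cg["strand"] == "-").sum()

    def test_unsatisfiable_plan_raises(self):
        with pytest.raises(DmrPlacementError):
            simulate_methylomes(
                _small_spec(
                    chrom_sizes={"chr1": 30_000},
                    dmr_plan=DmrPlan(n_dmrs=50, min_separation=2000),
                )
            )


class TestSimulateSegmentation:
    def test_covers_genome_disjointly(self):
        seg = simulate_segmentation({"chr1": 300_000}, seed=4)
        df = seg.intervals
        assert df["start"].iloc[0] == 0
        assert df["end"].iloc[-1] == 300_000
        assert (df["start"].iloc[1:].to_numpy() == df["end"].iloc[:-1].to_numpy()).all()


class TestSimulateExpression:
    def test_same_seed_identical(self):
        a = simulate_expression(seed=5)
        b = simulate_expression(seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_null_pvalues_not_enriched_below_alpha(self):
        table = simulate_expression(n_genes=200, effects=0.0, seed=6)
        pvals = []
        for gene, sub in table.groupby("gene"):
            per_subject = sub.groupby("subject").agg(
                {"delta_ct": "mean", "group": "first"}
            )
            pvals.append(
                rank_sum_test(
                    per_subject["delta_ct"].to_numpy(), per_subject["group"].to_numpy()
                )
            )
        pvals = np.asarray(pvals)
        assert (pvals < 0.05).mean() <= 0.08  # ~alpha with binomial slack at n=200
        assert pvals.mean() > 0.4  # roughly uniform, not left-shifted

    def test_strong_effect_detected_in_most_seeds(self):
        hits = 0
        for seed in range(20):
            table = simulate_expression(
                n_genes=1, effects=3.0, noise_sd=0.5, n_per_group=9, seed=seed
            )
            per_subject = table.groupby("subject").agg(
                {"delta_ct": "mean", "group": "first"}
            )
            p = rank_sum_test(
                per_subject["delta_ct"].to_numpy(), per_subject["group"].to_numpy()
            )
            hits += p < 0.05
        assert hits >= 19  # >= 95% power at effect 3.0, sd 0.5


class TestRecoveryScoring:
    def _truth(self, dmrs):
        return SyntheticTruth(
            dmrs=pd.DataFrame(
                dmrs, columns=["chrom", "start", "end", "direction", "delta"]
            ),
            true_ratios=pd.DataFrame(),
            spec=_small_spec(),
        )

    def test_perfect_match(self):
        truth = self._truth([("chr1", 100, 250, "hyper_old", 0.4)])
        called = truth.dmrs.copy()
        res = evaluate_dmr_recovery(called, truth)
        assert res.precision == 1.0 and res.recall == 1.0

    def test_no_calls(self):
        truth = self._truth([("chr1", 100, 250, "hyper_old", 0.4)])
        res = evaluate_dmr_recovery(truth.dmrs.iloc[:0], truth)
        assert res.precision is None
        assert res.recall == 0.0

    def test_one_call_spanning_two_truths(self):
        truth = self._truth(
            [
                ("chr1", 100, 200, "hyper_old", 0.4),
                ("chr1", 300, 400, "hyper_old", 0.4),
            ]
        )
        called = pd.DataFrame(
            [("chr1", 150, 350, "hyper_old")],
            columns=["chrom", "start", "end", "direction"],
        )
        res = evaluate_dmr_recovery(called, truth)
        assert res.precision == 1.0
        assert res.recall == 1.0  # both truths touched by the single call

    def test_direction_disagreement_not_a_match(self):
        truth = self._truth([("chr1", 100, 200, "hyper_old", 0.4)])
        called = pd.DataFrame(
            [("chr1", 120, 180, "hypo_old")],
            columns=["chrom", "start", "end", "direction"],
        )
        res = evaluate_dmr_recovery(called, truth)
        assert res.precision == 0.0 and res.recall == 0.0

    def test_end_to_end_recovery_small_scale(self):
        spec = SyntheticSpec(
            chrom_sizes={"chr1": 3_000_000},
            coverage_young=12,
            coverage_old=12,
            dmr_plan=DmrPlan(n_dmrs=12),
            control_sites=0,
            noncpg_sites=0,
            seed=9,
        )
        young, old, truth = simulate_methylomes(spec)
        from dmrscan.calling import call_dmrs

        _, dmrs = call_dmrs(pair_methylomes(young, old))
        res = evaluate_dmr_recovery(dmrs, truth)
        assert res.precision >= 0.8
        assert res.recall >= 0.7  # small-n variant of the full-scale check
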