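"""Per-CpG Fisher testing and DMC -> DMR clustering/scoring."""

import numpy as np
import pytest
from scipy.stats import fisher_exact

from dmrscan.calling import (
    call_dmcs,
    call_dmrs,
    cluster_dmcs,
    fisher_exact_two_sided,
    score_and_filter_dmrs,
    validate_dmrs,
)
from dmrscan.simulate import DmrPlan, SyntheticSpec, simulate_methylomes
from dmrscan.io import pair_methylomes

from conftest import make_pair
from oracles import fisher_two_sided_oracle


class TestFisherExact:
    def test_extreme_table(self):
        # all 11 tables with these margins enumerate to p = 2/184756
        p = fisher_exact_two_sided([0], [10], [10], [10])[0]
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_identical_tables_p_one(self):
        p = fisher_exact_two_sided([5], [10], [5], [10])[0]
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_moderate_difference(self):
        p = fisher_exact_two_sided([2], [10], [8], [10])[0]
        assert p == pytest.approx(fisher_two_sided_oracle(2, 10, 8, 10), rel=1e-9)
        assert p == pytest.approx(0.0230, abs=5e-4)

    def test_matches_scipy_on_random_tables(self, rng):
        t1 = rng.integers(1, 40, size=300)
        t2 = rng.integers(1, 40, size=300)
        m1 = rng.binomial(t1, 0.4)
        m2 = rng.binomial(t2, 0.6)
        ours = fisher_exact_two_sided(m1, t1, m2, t2)
        for i in range(300):
            table = [[m1[i], t1[i] - m1[i]], [m2[i], t2[i] - m2[i]]]
            assert ours[i] == pytest.approx(fisher_exact(table).pvalue, rel=1e-7)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([5], [4], [0], [10])


class TestCallDmcs:
    def test_significant_site_becomes_dmc(self):
        pair = make_pair([("chr1", 100, "+", 0, 10, 10, 10)])
        dmcs = call_dmcs(pair)
        assert len(dmcs) == 1
        assert dmcs.iloc[0]["delta"] == pytest.approx(1.0)
        assert dmcs.iloc[0]["direction"] == 1

    def test_identical_ratios_not_dmc(self):
        pair = make_pair([("chr1", 100, "+", 5, 10, 5, 10)])
        assert len(call_dmcs(pair)) == 0

    def test_swap_flips_direction_keeps_pvalue(self):
        pair = make_pair(
            [("chr1", p, "+", 1, 12, 10, 12) for p in range(100, 200, 10)]
        )
        fwd = call_dmcs(pair)
        rev = call_dmcs(pair.swapped())
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"])
        assert (fwd["direction"].to_numpy() == -rev["direction"].to_numpy()).all()

    def test_alpha_bounds_checked(self):
        pair = make_pair([("chr1", 100, "+", 0, 10, 10, 10)])
        with pytest.raises(ValueError):
            call_dmcs(pair, alpha=1.5)


def _dmc_pair(positions, direction=+1, cov=20):
    """Maximally significant DMCs at the given positions."""
    rows = []
    for p in positions:
        ym, om = (0, cov) if direction > 0 else (cov, 0)
        rows.append(("chr1", p, "+", ym, cov, om, cov))
    return make_pair(rows)


class TestClusterDmcs:
    def test_minimal_qualifying_chain(self):
        pair = _dmc_pair(range(100, 420, 40))  # 8 DMCs spaced 40 bp
        clusters = cluster_dmcs(call_dmcs(pair))
        assert len(clusters) == 1
        row = clusters.iloc[0]
        assert (row["n_dmc"], row["net"]) == (8, 8)

    def test_balanced_directions_fail_net(self):
        rows = []
        for i, p in enumerate(range(100, 180, 10)):  # 8 DMCs, 4 up + 4 down
            ym, om = (0, 20) if i % 2 == 0 else (20, 0)
            rows.append(("chr1", p, "+", ym, 20, om, 20))
        clusters = cluster_dmcs(call_dmcs(make_pair(rows)))
        assert clusters.empty

    def test_oversized_gap_splits_chain(self):
        # 9 DMCs with one 51-bp gap -> fragments of 5 and 4, both too small
        positions = [100, 110, 120, 130, 140, 191, 201, 211, 221]
        clusters = cluster_dmcs(call_dmcs(_dmc_pair(positions)))
        assert clusters.empty

    def test_gap_of_exactly_fifty_links(self):
        positions = [100 + 50 * i for i in range(8)]
        clusters = cluster_dmcs(call_dmcs(_dmc_pair(positions)))
        assert len(clusters) == 1

    def test_net_counts_from_mixed_directions(self):
        rows = []
        positions = list(range(100, 200, 10))  # 10 DMCs: 9 up, 1 down
        for i, p in enumerate(positions):
            ym, om = (20, 0) if i == 0 else (0, 20)
            rows.append(("chr1", p, "+", ym, 20, om, 20))
        clusters = cluster_dmcs(call_dmcs(make_pair(rows)))
        assert len(clusters) == 1
        assert clusters.iloc[0]["net"] == 8

    def test_empty_input_empty_output(self):
        import pandas as pd

        assert cluster_dmcs(pd.DataFrame(columns=["chrom", "pos", "direction"])).empty


class TestScoreAndFilter:
    def test_low_coverage_cluster_rejected(self):
        # coverage (8+8)/2 = 8 passes; (7+8)/2 = 7.5 fails
        passing = _dmc_pair(range(100, 180, 10), cov=8)
        dmrs = score_and_filter_dmrs(cluster_dmcs(call_dmcs(passing)), passing)
        assert len(dmrs) == 1
        rows = [("chr1", p, "+", 0, 7, 8, 8) for p in range(100, 180, 10)]
        failing = make_pair(rows)
        dmrs = score_and_filter_dmrs(cluster_dmcs(call_dmcs(failing)), failing)
        assert dmrs.empty

    def test_pooled_delta_boundary_inclusive(self):
        # 8 extreme DMCs diluted by filler sites to pooled delta exactly 0.10
        dmc_rows = [("chr1", 100 + 50 * i, "+", 0, 10, 10, 10) for i in range(8)]
        filler = [
            ("chr1", 101 + i, s, 5, 10, 5, 10)
            for i in range(36)
            for s in ("+", "-")
        ]  # 72 filler sites inside the span
        pair = make_pair(dmc_rows + filler)
        dmrs = score_and_filter_dmrs(cluster_dmcs(call_dmcs(pair)), pair)
        assert len(dmrs) == 1
        assert dmrs.iloc[0]["pooled_delta"] == pytest.approx(0.10)
        assert dmrs.iloc[0]["direction"] == "hyper_old"

    def test_pooled_delta_from_counts(self):
        pair = make_pair(
            [("chr1", 100 + 10 * i, "+", 1, 10, 9, 10) for i in range(8)]
        )
        dmrs = score_and_filter_dmrs(cluster_dmcs(call_dmcs(pair)), pair)
        assert dmrs.iloc[0]["pooled_delta"] == pytest.approx(0.8)

    def test_span_covers_first_to_last_dmc(self):
        pair = _dmc_pair(range(100, 180, 10))
        dmrs = score_and_filter_dmrs(cluster_dmcs(call_dmcs(pair)), pair)
        assert (dmrs.iloc[0]["start"], dmrs.iloc[0]["end"]) == (99, 170)

    def test_validator_accepts_called_output(self):
        pair = _dmc_pair(range(100, 180, 10))
        _, dmrs = call_dmrs(pair)
        validate_dmrs(dmrs)

    def test_validator_rejects_tampered_dmrs(self):
        pair = _dmc_pair(range(100, 180, 10))
        _, dmrs = call_dmrs(pair)
        dmrs.loc[0, "n_dmc"] = 3
        with pytest.raises(AssertionError):
            validate_dmrs(dmrs)


class TestNullBehaviour:
    def test_type_one_error_conservative_on_null(self):
        spec = SyntheticSpec(
            chrom_sizes={"chr1": 1_000_000},
            coverage_young=12,
            coverage_old=12,
            dmr_plan=DmrPlan(n_dmrs=0),
            control_sites=0,
            noncpg_sites=0,
            seed=11,
        )
        young, old, _ = simulate_methylomes(spec)
        pair = pair_methylomes(young, old)
        dmcs = call_dmcs(pair)
        assert len(dmcs) / len(pair) <= 0.05

    def test_swap_symmetry_on_dmrs(self):
        spec = SyntheticSpec(
            chrom_sizes={"chr1": 2_000_000},
            coverage_young=12,
            coverage_old=12,
            dmr_plan=DmrPlan(n_dmrs=10),
            control_sites=0,
            noncpg_sites=0,
            seed=3,
        )
        young, old, _ = simulate_methylomes(spec)
        pair = pair_methylomes(young, old)
        _, fwd = call_dmrs(pair)
        _, rev = call_dmrs(pair.swapped())
        assert len(fwd) == len(rev)
        assert fwd["start"].tolist() == rev["start"].tolist()
        np.testing.assert_allclose(fwd["pooled_delta"], -rev["pooled_delta"])
        flipped = {"hyper_old": "hypo_old", "hypo_old": "hyper_old"}
        assert [flipped[d] for d in fwd["direction"]] == rev["direction"].tolist()
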