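import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

import stageomics as so
from stageomics.design import StageDesign

from conftest import toy_methylome

TWO_STAGE = StageDesign(("A", "B"), 1)


class TestRegionLevel:
    def test_single_site_ratio(self):
        m = toy_methylome([100], "CHH", [[5, 5]], [[20, 20]], TWO_STAGE)
        assert so.region_methylation_level(m, "ChrT", 0, 200, "CHH") == \
            pytest.approx(0.25)

    def test_pooled_not_averaged(self):
        # sites 3/10 and 7/10 pool to (3+7)/(10+10) = 0.5
        m = toy_methylome([100, 150], "CHH", [[3, 3], [7, 7]],
                          [[10, 10], [10, 10]], TWO_STAGE)
        assert so.region_methylation_level(m, "ChrT", 0, 200, "CHH") == \
            pytest.approx(0.5)

    def test_empty_interval_undefined_not_zero(self):
        m = toy_methylome([100], "CHH", [[5, 5]], [[20, 20]], TWO_STAGE)
        assert np.isnan(so.region_methylation_level(m, "ChrT", 500, 600, "CHH"))

    def test_pooling_invariance_over_disjoint_union(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(1000, size=30, replace=False))
        total = rng.integers(1, 40, size=(30, 2))
        meth = rng.binomial(total, 0.3)
        m = toy_methylome(pos, ["CG"] * 30, meth, total, TWO_STAGE)
        whole = so.region_methylation_level(m, "ChrT", 0, 1000)
        parts_meth = parts_total = 0
        for lo, hi in [(0, 250), (250, 700), (700, 1000)]:
            mask = (pos >= lo) & (pos < hi)
            parts_meth += meth[mask].sum()
            parts_total += total[mask].sum()
        assert whole == pytest.approx(parts_meth / parts_total)

    def test_zero_coverage_sites_excluded(self):
        m = toy_methylome([100, 150], "CG", [[5, 0], [0, 0]],
                          [[20, 0], [0, 0]], TWO_STAGE)
        assert so.region_methylation_level(m, "ChrT", 0, 200, "CG", stage="B") \
            != so.region_methylation_level(m, "ChrT", 0, 200, "CG", stage="A")
        assert np.isnan(so.region_methylation_level(m, "ChrT", 0, 200, "CG",
                                                    stage="B"))


class TestMetagene:
    def test_uniform_methylation_gives_flat_profile(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(9000, size=200, replace=False)) + 500
        total = np.full((200, 2), 40)
        meth = total // 2
        m = toy_methylome(pos, ["CG"] * 200, meth, total, TWO_STAGE)
        genes = [so.GeneModel("g1", "ChrT", 3000, 6000, "+")]
        prof = so.metagene_profile(m, genes, n_body_bins=10, flank_bp=2000,
                                   flank_bin_bp=500, contexts=("CG",))
        covered = prof.dropna(subset=["level"])
        assert np.allclose(covered["level"], 0.5)

    def test_minus_strand_sites_mirrored(self):
        # a site right of a minus-strand gene is in its 5' (upstream) flank
        m = toy_methylome([6100], "CHH", [[4, 4]], [[10, 10]], TWO_STAGE)
        genes = [so.GeneModel("g1", "ChrT", 3000, 6000, "-")]
        prof = so.metagene_profile(m, genes, n_body_bins=4, flank_bp=2000,
                                   flank_bin_bp=500, contexts=("CHH",),
                                   stages=["A"])
        hit = prof.dropna(subset=["level"])
        assert (hit["segment"] == "upstream").all()

    def test_hand_placed_sites_match_pooled_ratios(self):
        # 4 sites: upstream flank, two body positions, downstream flank
        design = TWO_STAGE
        pos = [2600, 3100, 3600, 4100]
        meth = [[2, 2], [3, 3], [5, 5], [9, 9]]
        total = [[10, 10]] * 4
        m = toy_methylome(pos, ["CG"] * 4, meth, total, design)
        genes = [so.GeneModel("g1", "ChrT", 3000, 4000, "+")]
        prof = so.metagene_profile(m, genes, n_body_bins=2, flank_bp=1000,
                                   flank_bin_bp=500, contexts=("CG",),
                                   stages=["A"])
        prof = prof.set_index("bin_index")["level"]
        assert prof.loc[1] == pytest.approx(0.2)   # upstream bin [2500,3000)
        assert prof.loc[2] == pytest.approx(0.3)   # body first half
        assert prof.loc[3] == pytest.approx(0.5)   # body second half
        assert prof.loc[4] == pytest.approx(0.9)   # downstream [4000,4500)


def _dmr_methylome(n_sites, level_a, level_b, depth=30, start=100, width=100,
                   context="CHH", seed=0):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(start, start + width), n_sites,
                             replace=False))
    total = np.full((n_sites, 2), depth * 3)  # pooled 3-replicate depth
    meth = np.column_stack([
        rng.binomial(total[:, 0], level_a),
        rng.binomial(total[:, 1], level_b),
    ])
    return toy_methylome(pos, [context] * n_sites, meth, total, TWO_STAGE)


class TestCallDmrs:
    def test_null_identical_stages(self):
        rng = np.random.default_rng(2)
        pos = np.arange(100, 300, 10)
        total = np.full((20, 2), 90)
        meth_col = rng.binomial(90, 0.3, size=20)
        meth = np.column_stack([meth_col, meth_col])  # identical stages
        m = toy_methylome(pos, ["CG"] * 20, meth, total, TWO_STAGE)
        dmrs = so.call_dmrs(m, "A", "B", min_windows=1)
        assert dmrs.empty

    def test_planted_window_detected_with_fisher_oracle(self):
        m = _dmr_methylome(10, 0.1, 0.6)
        dmrs = so.call_dmrs(m, "A", "B", window_bp=200, step_bp=100,
                            min_windows=1)
        assert len(dmrs) == 1
        rec = dmrs.iloc[0]
        assert rec["delta"] == pytest.approx(0.5, abs=0.1)
        assert rec["n_sites"] == 10
        # oracle: Fisher exact on the pooled 2x2 table
        ma, ta = m.stage_counts("A")
        mb, tb = m.stage_counts("B")
        expected_p = fisher_exact([[ma.sum(), ta.sum() - ma.sum()],
                                   [mb.sum(), tb.sum() - mb.sum()]])[1]
        assert rec["p_value"] == pytest.approx(expected_p, rel=1e-9)
        assert rec["q_value"] < 0.05

    def test_min_sites_gate(self):
        m = _dmr_methylome(3, 0.0, 1.0)
        dmrs = so.call_dmrs(m, "A", "B", min_windows=1)
        assert dmrs.empty

    def test_reported_dmrs_respect_gates(self, small_dataset):
        meth = small_dataset.methylome
        dmrs = so.call_dmrs(meth, "S5", "S6")
        assert (dmrs["n_sites"] >= 4).all()
        assert (dmrs["delta"].abs() >= 0.1).all()
        assert (dmrs["q_value"] < 0.05).all()

    def test_min_windows_consistency_rule(self):
        # a single significant window is dropped at min_windows=2
        m = _dmr_methylome(10, 0.1, 0.6, width=90)
        single = so.call_dmrs(m, "A", "B", window_bp=100, step_bp=100,
                              min_windows=2)
        assert single.empty
        lone = so.call_dmrs(m, "A", "B", window_bp=100, step_bp=100,
                            min_windows=1)
        assert len(lone) == 1


class TestPromoterDmrGenes:
    GENES = [so.GeneModel("g1", "ChrT", 10000, 12000, "+"),
             so.GeneModel("g2", "ChrT", 30000, 31000, "+")]

    def _dmrs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "context"])

    def test_overlap_and_flags(self):
        dmrs = self._dmrs([("ChrT", 8100, 8200, "CHH"),
                           ("ChrT", 9500, 9600, "CG")])
        mapping, flags = so.promoter_dmr_genes(dmrs, self.GENES, 2000)
        assert set(mapping) == {"g1"} and len(mapping["g1"]) == 2
        assert flags.loc["g1", ["CG", "CHH"]].all()
        assert not flags.loc["g1", "CHG"]
        assert not flags.loc["g2", "any"]

    def test_half_open_boundary(self):
        # promoter [8000, 10000): a DMR starting exactly at 10000 misses it
        dmrs = self._dmrs([("ChrT", 10000, 10100, "CHH")])
        mapping, flags = so.promoter_dmr_genes(dmrs, self.GENES, 2000)
        assert not flags["any"].any()
        assert mapping == {}


class TestSirnaRpm:
    DESIGN = StageDesign(("A", "B"), 1)

    def _clusters(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                           "A_R1", "B_R1"])

    def test_rpm_definition(self):
        clusters = self._clusters([("ChrT", 100, 200, "c1", 50, 10)])
        regions = pd.DataFrame({"chrom": ["ChrT"], "start": [0], "end": [500]})
        rpm = so.sirna_rpm_in_regions(clusters, regions,
                                      {("A", 1): 1_000_000, ("B", 1): 1_000_000})
        assert rpm.loc[0, "A_R1"] == pytest.approx(50.0)
        assert rpm.loc[0, "B_R1"] == pytest.approx(10.0)

    def test_empty_region_zero(self):
        clusters = self._clusters([("ChrT", 5000, 5100, "c1", 50, 10)])
        regions = pd.DataFrame({"chrom": ["ChrT"], "start": [0], "end": [500]})
        rpm = so.sirna_rpm_in_regions(clusters, regions,
                                      {("A", 1): 1e6, ("B", 1): 1e6})
        assert (rpm.to_numpy() == 0).all()

    def test_midpoint_rule_counts_straddler_once_fully(self):
        # cluster [450, 650): midpoint 550 inside [500, 1000) -> full count
        clusters = self._clusters([("ChrT", 450, 650, "c1", 40, 40)])
        regions = pd.DataFrame({"chrom": ["ChrT", "ChrT"],
                                "start": [0, 500], "end": [500, 1000]})
        rpm = so.sirna_rpm_in_regions(clusters, regions,
                                      {("A", 1): 1e6, ("B", 1): 1e6})
        assert rpm.loc[0, "A_R1"] == 0.0
        assert rpm.loc[1, "A_R1"] == pytest.approx(40.0)

    def test_nonpositive_totals_rejected(self):
        clusters = self._clusters([("ChrT", 0, 10, "c1", 1, 1)])
        regions = pd.DataFrame({"chrom": ["ChrT"], "start": [0], "end": [50]})
        with pytest.raises(so.InputError):
            so.sirna_rpm_in_regions(clusters, regions, {("A", 1): 0,
                                                        ("B", 1): 1e6})
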