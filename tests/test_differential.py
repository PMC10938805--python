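import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stageomics as so
from stageomics.design import StageDesign
from stageomics.errors import InputError

from conftest import make_feature_table


def bh_oracle(p):
    """Step-up from the definition: q_(i) = min_{j>=i} p_(j)*m/j, capped."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    vals = ps * m / np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        q[order[i]] = min(1.0, vals[i:].min())
    return q


class TestBHAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.04, 0.01], [0.04, 0.02]),
    ])
    def test_worked_examples(self, p, expected):
        assert so.bh_adjust(p) == pytest.approx(expected, abs=1e-15)

    def test_empty_vector(self):
        assert so.bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            so.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_definition_oracle(self, p):
        assert np.allclose(so.bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_qvalues_dominate_pvalues_and_capped(self, p):
        q = so.bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all() and (q <= 1.0).all()


def _two_stage_table(mean_a, mean_b, n_features=1, noise=0.0, seed=0,
                     base=None):
    """Table with 11 stages where only S1 and S11 matter."""
    rng = np.random.default_rng(seed)
    design = StageDesign()
    base = base if base is not None else (mean_a + mean_b) / 2
    values = np.full((n_features, 33), float(base))
    values[:, :3] = mean_a
    values[:, -3:] = mean_b
    values *= np.exp2(rng.normal(scale=noise, size=values.shape))
    return make_feature_table(values, design=design)


class TestCallDifferential:
    def test_fold_change_and_significance(self):
        # replicate means 10 vs 40 with tiny noise: fc = 4, q small
        table = _two_stage_table(10, 40, n_features=50, noise=0.02, seed=1)
        rec = so.call_differential(table, "S1", "S11", pseudocount=0.0)
        assert np.allclose(rec["log2fc"], 2.0, atol=0.1)
        assert rec["significant"].all()
        assert (rec["direction"] == "up").all()

    def test_fc_gate_blocks_small_fold_changes(self):
        table = _two_stage_table(10, 15, n_features=50, noise=0.01, seed=2)
        rec = so.call_differential(table, "S1", "S11")
        assert (rec["q_value"] < 0.05).all()      # highly significant t
        assert not rec["significant"].any()        # but FC 1.5 < 2

    def test_fdr_gate_blocks_noisy_features(self):
        table = _two_stage_table(10, 100, n_features=20, noise=3.0, seed=3)
        rec = so.call_differential(table, "S1", "S11")
        weak = rec[rec["q_value"] >= 0.05]
        assert not weak["significant"].any()

    def test_unknown_stage_rejected(self):
        table = _two_stage_table(1, 2)
        with pytest.raises(InputError):
            so.call_differential(table, "S1", "S99")

    def test_all_zero_features_excluded(self):
        design = StageDesign(("A", "B"), 3)
        values = np.array([[0, 0, 0, 0, 0, 0], [1, 1, 1, 9, 9, 9.0]])
        table = make_feature_table(values, design=design)
        rec = so.call_differential(table, "A", "B")
        assert rec["feature_id"].tolist() == ["f2"]

    def test_stage_swap_symmetry(self):
        table = _two_stage_table(10, 80, n_features=20, noise=0.5, seed=4)
        ab = so.call_differential(table, "S1", "S11")
        ba = so.call_differential(table, "S11", "S1")
        assert np.allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)
        assert np.allclose(ab["p_value"], ba["p_value"], atol=1e-12)

    def test_threshold_monotonicity(self):
        table = _two_stage_table(10, 60, n_features=100, noise=1.0, seed=5)
        loose = so.call_differential(table, "S1", "S11", q_threshold=0.2)
        strict = so.call_differential(table, "S1", "S11", q_threshold=0.01)
        assert set(strict.loc[strict["significant"], "feature_id"]) <= \
            set(loose.loc[loose["significant"], "feature_id"])
        fc_high = so.call_differential(table, "S1", "S11", fc_threshold=8)
        fc_low = so.call_differential(table, "S1", "S11", fc_threshold=2)
        assert set(fc_high.loc[fc_high["significant"], "feature_id"]) <= \
            set(fc_low.loc[fc_low["significant"], "feature_id"])


class TestAllPairs:
    def test_pair_count(self):
        table = _two_stage_table(5, 5, n_features=3, noise=0.1, seed=6)
        rec = so.differential_all_pairs(table)
        pairs = rec.groupby(["stage_a", "stage_b"]).size()
        assert len(pairs) == 55  # C(11, 2)

    def test_single_pair_feature(self):
        # differential only between S1 and S11 (every pair involving the
        # intermediate level stays below the 2x fold-change gate)
        table = _two_stage_table(10, 36, n_features=1, noise=0.0, base=19)
        # tiny deterministic jitter so variances are nonzero
        rng = np.random.default_rng(8)
        v = table.values.to_numpy() * np.exp2(rng.normal(scale=0.01, size=(1, 33)))
        table = make_feature_table(v)
        rec = so.differential_all_pairs(table)
        sig = rec[rec["significant"]]
        assert set(zip(sig["stage_a"], sig["stage_b"])) == {("S1", "S11")}
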