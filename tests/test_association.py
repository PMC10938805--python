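import numpy as np
import pandas as pd
import pytest

import stageomics as so
from stageomics.errors import InputError


def pearson_oracle(x, y):
    """Two-pass covariance oracle (independent of scipy)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5


class TestPearson:
    def test_collinear(self):
        x = np.arange(1.0, 12.0)
        r, p = so.pearson_r(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        r, _p = so.pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_undefined(self):
        r, p = so.pearson_r([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r) and np.isnan(p)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            so.pearson_r([1, 2, 3], [1, 2, 3, 4])

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x, y = rng.normal(size=(2, 11))
            r, _ = so.pearson_r(x, y)
            assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(5, 11)))
        b = pd.DataFrame(rng.normal(size=(4, 11)))
        r, p = so.correlation_matrix(a, b)
        for i in range(5):
            for j in range(4):
                rr, pp = so.pearson_r(a.iloc[i], b.iloc[j])
                assert r.iloc[i, j] == pytest.approx(rr, abs=1e-12)
                assert p.iloc[i, j] == pytest.approx(pp, rel=1e-9)


def _means(rows, ids, stages=11):
    return pd.DataFrame(rows, index=ids, columns=[f"S{i+1}" for i in range(stages)])


class TestBuildEdges:
    def test_exact_linear_relation_retained(self):
        x = np.linspace(1, 5, 11)
        feats = _means([2 * x + 1], ["g1"])
        mets = _means([x], ["m1"])
        edges = so.build_association_edges(feats, mets, "transcript-metabolite")
        assert len(edges) == 1
        rec = edges.iloc[0]
        assert (rec["source"], rec["target"], rec["sign"]) == ("g1", "m1", "+")
        assert rec["r"] == pytest.approx(1.0)

    def test_r_gate_blocks_significant_but_weak(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 11)
        y = 0.55 * x + rng.normal(scale=0.25, size=11) + 2
        r, _ = so.pearson_r(x, y)
        assert abs(r) < 0.85
        edges = so.build_association_edges(_means([y], ["g1"]),
                                           _means([x], ["m1"]), "t-m")
        assert edges.empty

    def test_feature_restriction(self):
        x = np.linspace(1, 5, 11)
        feats = _means([x, 3 * x], ["g1", "g2"])
        mets = _means([x], ["m1"])
        edges = so.build_association_edges(feats, mets, "t-m",
                                           feature_ids=["g2"])
        assert edges["source"].tolist() == ["g2"]


class TestConsistencyFilter:
    def _edges(self, rows, layer):
        return pd.DataFrame(
            rows, columns=["source", "target", "r", "p_value", "q_value",
                           "sign"]).assign(layer=layer)

    def test_discordant_pair_removed_concordant_kept(self):
        tr = self._edges([("g1", "m1", 0.9, 1e-6, 1e-5, "+"),
                          ("g2", "m1", 0.9, 1e-6, 1e-5, "+")],
                         "transcript-metabolite")
        pr = self._edges([("pr.g1", "m1", -0.9, 1e-6, 1e-5, "-"),
                          ("pr.g2", "m1", 0.88, 1e-6, 1e-5, "+")],
                         "protein-metabolite")
        mapping = pd.Series({"pr.g1": "g1", "pr.g2": "g2"})
        db = so.consistency_filter(tr, pr, mapping)
        assert db.removed_pairs[["gene", "metabolite"]].to_numpy().tolist() == \
            [["g1", "m1"]]
        kept = set(zip(db.edges["source"], db.edges["target"]))
        assert ("g1", "m1") not in kept and ("pr.g1", "m1") not in kept
        assert {("g2", "m1"), ("pr.g2", "m1")} <= kept

    def test_gene_without_protein_passes_through(self):
        tr = self._edges([("g3", "m1", 0.95, 1e-8, 1e-7, "+")],
                         "transcript-metabolite")
        pr = self._edges([], "protein-metabolite")
        db = so.consistency_filter(tr, pr, pd.Series(dtype=object))
        assert db.removed_pairs.empty
        assert len(db.edges) == 1

    def test_unknown_protein_rejected(self):
        tr = self._edges([], "transcript-metabolite")
        pr = self._edges([("pr.gX", "m1", 0.9, 1e-6, 1e-5, "+")],
                         "protein-metabolite")
        with pytest.raises(InputError):
            so.consistency_filter(tr, pr, pd.Series(dtype=object))

    def test_database_closure_on_metabolite_removal(self):
        tr = self._edges([("g1", "m1", 0.9, 1e-6, 1e-5, "+"),
                          ("g1", "m2", 0.9, 1e-6, 1e-5, "+")],
                         "transcript-metabolite")
        db = so.consistency_filter(tr, self._edges([], "protein-metabolite"),
                                   pd.Series(dtype=object))
        smaller = db.drop_metabolite("m1")
        assert set(smaller.edges["target"]) == {"m2"}


class TestMethylationExpression:
    def test_identical_series_perfect_edge(self):
        x = np.linspace(0.1, 0.5, 11)
        prom = _means([x], ["g1"])
        expr = _means([x * 100], ["g1"])
        edges = so.methylation_expression_edges(prom, expr)
        assert len(edges) == 1
        assert edges.iloc[0]["r"] == pytest.approx(1.0)
        assert edges.iloc[0]["sign"] == "+"
        assert edges.iloc[0]["target"] == "g1"

    def test_constant_or_undefined_promoter_skipped(self):
        prom = _means([[0.3] * 11, [np.nan] + [0.2] * 10], ["g1", "g2"])
        expr = _means([np.linspace(1, 5, 11)] * 2, ["g1", "g2"])
        edges = so.methylation_expression_edges(prom, expr)
        assert edges.empty

    def test_coupled_promoters_recovered(self, small_dataset):
        ds = small_dataset
        prom = so.promoter_level_matrix(ds.methylome, ds.genes, 2000)
        expr = ds.transcriptome.stage_means()
        edges = so.methylation_expression_edges(
            prom.loc[list(ds.truth.coupled_promoters.index)], expr)
        detected = edges.set_index("target")["sign"]
        hits = sum(1 for g, s in ds.truth.coupled_promoters.items()
                   if g in detected.index and detected.loc[g] == s)
        assert hits / len(ds.truth.coupled_promoters) >= 0.9


class TestGenomeMethylationCorrelation:
    def test_sign_pattern_on_constructed_series(self):
        stages = [f"S{i+1}" for i in range(11)]
        rising = pd.Series(np.linspace(0.2, 0.4, 11), index=stages)
        arch = so.make_archetypes(11)
        dam = pd.DataFrame(
            [np.exp2(8 + arch.loc["III"]), np.exp2(8 + arch.loc["I"])],
            index=["m_up", "m_down"])
        dam.columns = stages
        edges, _ = so.genome_methylation_dam_correlation(rising, dam)
        r = edges.set_index("target")["r"]
        assert r["m_up"] > 0 > r["m_down"]

    def test_cluster_summary_medians(self):
        stages = [f"S{i+1}" for i in range(11)]
        rising = pd.Series(np.linspace(0.2, 0.4, 11), index=stages)
        arch = so.make_archetypes(11)
        dam = pd.DataFrame([arch.loc["I"] + 2, arch.loc["I"] + 2.1,
                            arch.loc["III"] + 2], index=["a", "b", "c"])
        dam.columns = stages
        clusters = pd.DataFrame({"feature_id": ["a", "b", "c"],
                                 "cluster_label": ["I", "I", "III"],
                                 "centroid_distance": 0.0})
        _, summary = so.genome_methylation_dam_correlation(rising, dam, clusters)
        med = summary.set_index("cluster_label")["median_r"]
        assert med["I"] < 0 < med["III"]
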