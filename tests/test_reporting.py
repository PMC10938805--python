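import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import yaml

import stageomics as so
from stageomics.errors import InputError
from stageomics.reporting import read_network_tsv


def _database(edge_rows, clusters=None, class_of=None):
    edges = pd.DataFrame(edge_rows,
                         columns=["source", "target", "r", "q_value", "sign"])
    edges["layer"] = "transcript-metabolite"
    edges["p_value"] = edges["q_value"] / 10
    return so.GeneMetaboliteDatabase(
        edges=edges, removed_pairs=pd.DataFrame(),
        metabolite_clusters=clusters, class_of=class_of)


CLUSTERS = pd.DataFrame({"feature_id": ["m1", "m2"],
                         "cluster_label": ["I", "V"],
                         "centroid_distance": [0.1, 0.2]})


class TestExportNetwork:
    EDGES = [("g1", "m1", 0.9, 1e-4, "+"), ("g2", "m1", -0.9, 1e-4, "-"),
             ("g3", "m2", 0.95, 1e-5, "+")]

    def test_one_file_per_cluster_including_empty(self, tmp_path):
        db = _database(self.EDGES, clusters=CLUSTERS)
        paths = so.export_network(db, tmp_path, group_by="cluster",
                                  fmt="graphml")
        assert len(paths) == 8
        g1 = nx.read_graphml(paths["I"])
        assert set(g1.nodes) == {"g1", "g2", "m1"}
        assert g1["g1"]["m1"]["r"] == pytest.approx(0.9)
        empty = nx.read_graphml(paths["II"])
        assert len(empty) == 0

    def test_tsv_round_trip_preserves_edge_multiset(self, tmp_path):
        db = _database(self.EDGES, clusters=CLUSTERS)
        paths = so.export_network(db, tmp_path, group_by="cluster", fmt="tsv")
        frames = [df for df in (read_network_tsv(p) for p in paths.values())
                  if len(df)]
        back = pd.concat(frames, ignore_index=True)
        orig = db.edges.sort_values(["source", "target"]).reset_index(drop=True)
        back = back[orig.columns].sort_values(["source", "target"]) \
            .reset_index(drop=True)
        pd.testing.assert_frame_equal(back, orig, check_exact=False, rtol=1e-9)

    def test_empty_database_valid_files(self, tmp_path):
        db = _database([], clusters=CLUSTERS)
        paths = so.export_network(db, tmp_path, group_by="cluster")
        assert len(paths) == 8
        assert all(len(nx.read_graphml(p)) == 0 for p in paths.values())

    def test_unknown_format_rejected(self, tmp_path):
        db = _database(self.EDGES, clusters=CLUSTERS)
        with pytest.raises(InputError):
            so.export_network(db, tmp_path, fmt="gexf")


class TestChromosomeClassCounts:
    def test_distinct_gene_counting_and_bucketing(self):
        genes = [so.GeneModel("g1", "Chr1", 0, 10, "+"),
                 so.GeneModel("g2", "Chr1", 20, 30, "+")]
        class_of = pd.Series({"m1": "Amino acid", "m2": "Amino acid",
                              "m3": "Amino acid"})
        edges = [("g1", "m1", 0.9, 1e-4, "+"), ("g2", "m1", 0.9, 1e-4, "+"),
                 ("g2", "m2", 0.9, 1e-4, "+"), ("g2", "m3", 0.9, 1e-4, "+"),
                 ("gX", "m1", 0.9, 1e-4, "+")]  # gX not annotated
        db = _database(edges, class_of=class_of)
        table = so.chromosome_class_counts(db, genes)
        assert table.loc["Amino acid", "Chr1"] == 2   # g2 counted once
        assert table.loc["Amino acid", "Others"] == 1  # unannotated bucket


@pytest.fixture(scope="module")
def small_run(tmp_path_factory):
    sim = so.SimulationConfig(
        seed=7, n_metabolites=60, n_genes=300, n_proteins=120,
        n_planted_edges=40, n_planted_dmrs=15, n_coupled_promoters=15,
        sirna_background_clusters=40)
    out = tmp_path_factory.mktemp("small") / "run"
    manifest = so.run_pipeline(so.PipelineConfig(seed=7, simulation=sim), out)
    return manifest, out


class TestRunPipeline:
    def test_manifest_lists_all_outputs(self, small_run):
        manifest, out = small_run
        for name, meta in manifest["outputs"].items():
            assert (out / meta["path"]).exists(), name

    def test_manifest_counts_match_files(self, small_run):
        manifest, out = small_run
        for name, meta in manifest["outputs"].items():
            if meta["n_records"] is None or not meta["path"].endswith(".tsv"):
                continue
            n_lines = sum(1 for _ in open(out / meta["path"]))
            assert n_lines == meta["n_records"] + 1, name  # header line

    def test_manifest_json_written(self, small_run):
        _, out = small_run
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["software"] == "stageomics"
        assert manifest["mode"] == "synthetic"

    def test_real_mode_round_trips_synthetic_outputs(self, small_dataset,
                                                     tmp_path):
        paths = so.write_dataset(small_dataset, tmp_path / "inputs")
        reports = {k.split(":", 1)[1]: v for k, v in paths.items()
                   if k.startswith("cytosine:")}
        cr = {name.replace("cytosine_", "").replace(".txt", ""): p
              for name, p in reports.items()}
        config = so.PipelineConfig(mode="real", seed=7, paths={
            "metabolome": paths["metabolome"],
            "proteome": paths["proteome"],
            "transcriptome": paths["transcriptome"],
            "genes": paths["genes"],
            "sirna": paths["sirna_clusters"],
            "cytosine_reports": cr,
        })
        manifest = so.run_pipeline(config, tmp_path / "out")
        assert manifest["mode"] == "real"
        # same underlying data as the synthetic run: DAM counts must agree
        dams = pd.read_csv(tmp_path / "out" / "differential_metabolome.tsv",
                           sep="\t")
        assert dams["significant"].sum() > 0

    def test_missing_real_input_removes_partial_outputs(self, tmp_path):
        config = so.PipelineConfig(mode="real", paths={})
        out = tmp_path / "fail_run"
        with pytest.raises(InputError):
            so.run_pipeline(config, out)
        assert not out.exists()

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = {
            "mode": "synthetic", "seed": 3,
            "simulation": {"seed": 3, "n_metabolites": 20, "n_genes": 50,
                           "n_proteins": 10, "n_planted_edges": 5,
                           "n_planted_dmrs": 2, "n_coupled_promoters": 2},
            "dmr_stage_pairs": [["S5", "S6"]],
            "r_threshold": 0.8,
        }
        p = tmp_path / "config.yaml"
        p.write_text(yaml.safe_dump(cfg))
        loaded = so.PipelineConfig.from_yaml(p)
        assert loaded.seed == 3
        assert loaded.r_threshold == 0.8
        assert loaded.simulation.n_genes == 50
        assert loaded.default_dmr_pairs() == [("S5", "S6")]


class TestCli:
    def test_simulate_and_run_all(self, tmp_path):
        from click.testing import CliRunner

        from stageomics.cli import main

        cfg = {
            "mode": "synthetic", "seed": 2,
            "simulation": {"seed": 2, "n_metabolites": 20, "n_genes": 60,
                           "n_proteins": 20, "n_planted_edges": 8,
                           "n_planted_dmrs": 3, "n_coupled_promoters": 3,
                           "sirna_background_clusters": 10},
        }
        p = tmp_path / "config.yaml"
        p.write_text(yaml.safe_dump(cfg))
        runner = CliRunner()
        res = runner.invoke(main, ["simulate", "--config", str(p),
                                   "--out-dir", str(tmp_path / "sim")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "sim" / "metabolome.tsv").exists()
        res = runner.invoke(main, ["run-all", "--config", str(p),
                                   "--out-dir", str(tmp_path / "run")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "run" / "manifest.json").exists()
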