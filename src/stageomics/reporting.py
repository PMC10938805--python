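"""Pipeline orchestration, exports and ground-truth recovery metrics.

``run_pipeline`` executes the whole analysis — simulate (or load) ->
stage-pairwise differential calling on all three layers -> trend clustering
-> methylation (global levels, metagene profile, DMRs, promoter overlap,
siRNA RPM) -> association database (edges, consistency filter, methylation
couplings) -> adjacent-stage transitions -> network/summary exports — and
writes a JSON manifest. With a synthetic dataset it also writes a recovery
report (edge/DMR sensitivity and FDR, cluster ARI, coupling sign recovery).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._intervals import overlap_interval_pairs
from .association import (
    GeneMetaboliteDatabase,
    build_association_edges,
    consistency_filter,
    genome_methylation_dam_correlation,
    methylation_expression_edges,
)
from .design import StageDesign
from .differential import differential_all_pairs, differential_features
from .errors import InputError
from .io import (
    FLOAT_FORMAT,
    FeatureTable,
    Methylome,
    read_gene_annotation,
    read_sirna_clusters,
    read_stage_table,
)
from .methylation import (
    call_dmrs,
    metagene_profile,
    promoter_dmr_genes,
    promoter_level_matrix,
    sirna_rpm_in_regions,
    stage_level_series,
)
from .simulate import SimulationConfig, SimulatedDataset, simulate_multiomics
from .transitions import (
    class_transition_table,
    next_stage_increases,
    transition_correlated_degs,
)
from .trends import cluster_dam_trends

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# exports


def export_network(
    database: GeneMetaboliteDatabase,
    out_dir,
    group_by: str = "cluster",
    fmt: str = "graphml",
) -> dict[str, str]:
    """Bipartite gene/metabolite network per metabolite group.

    ``group_by='cluster'`` writes one file per trend cluster label (empty
    groups become empty graphs); ``group_by='class'`` groups by metabolite
    class. TSV edge lists round-trip losslessly via pandas.
    """
    if fmt not in ("graphml", "tsv"):
        raise InputError(f"unknown network format {fmt!r}")
    if group_by == "cluster":
        if database.metabolite_clusters is None:
            raise InputError("database carries no cluster assignments")
        member_of = database.metabolite_clusters.set_index(
            "feature_id")["cluster_label"]
        groups = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    elif group_by == "class":
        if database.class_of is None:
            raise InputError("database carries no metabolite classes")
        member_of = database.class_of
        groups = sorted(member_of.dropna().unique())
    else:
        raise InputError(f"unknown group_by {group_by!r}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges = database.edges
    group_of = member_of.reindex(edges["target"]).to_numpy()
    paths: dict[str, str] = {}
    for group in groups:
        sub = edges[group_of == group]
        safe = str(group).replace("/", "_").replace(" ", "_")
        if fmt == "tsv":
            path = out_dir / f"network_{group_by}_{safe}.tsv"
            sub.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        else:
            graph = nx.Graph()
            for rec in sub.itertuples(index=False):
                graph.add_node(rec.source, kind="gene" if not
                               str(rec.source).startswith("pr.") else "protein")
                graph.add_node(rec.target, kind="metabolite")
                graph.add_edge(rec.source, rec.target, r=float(rec.r),
                               q=float(rec.q_value), sign=rec.sign,
                               layer=rec.layer)
            path = out_dir / f"network_{group_by}_{safe}.graphml"
            nx.write_graphml(graph, path)
        paths[str(group)] = str(path)
    return paths


def read_network_tsv(path) -> pd.DataFrame:
    """Round-trip reader for TSV edge lists written by :func:`export_network`."""
    return pd.read_csv(path, sep="\t")


def chromosome_class_counts(
    database: GeneMetaboliteDatabase, gene_models,
) -> pd.DataFrame:
    """Class x chromosome matrix of distinct correlated genes.

    A gene counts once per metabolite class it has >= 1 edge to, on its own
    chromosome; genes absent from the annotation fall in the "Others" column.
    """
    chrom_of = {g.gene_id: g.chrom for g in gene_models}
    ge = database.gene_edges()
    if database.class_of is None:
        raise InputError("database carries no metabolite classes")
    cls = database.class_of.reindex(ge["target"]).fillna("Others").to_numpy()
    chrom = np.array([chrom_of.get(g, "Others") for g in ge["source"]])
    df = pd.DataFrame({"gene": ge["source"].to_numpy(), "class": cls,
                       "chrom": chrom}).drop_duplicates()
    table = df.pivot_table(index="class", columns="chrom", values="gene",
                           aggfunc="nunique", fill_value=0)
    table.index.name = "metabolite_class"
    return table.sort_index()


# ---------------------------------------------------------------------------
# ground-truth recovery


def edge_recovery(edges: pd.DataFrame, truth,
                  layer: str = "transcript-metabolite") -> dict[str, float]:
    """Sensitivity and empirical FDR of retained edges vs ground truth.

    Sensitivity is scored against the explicitly planted couplings; the FDR
    counts retained edges whose underlying mean series are *not* truly
    correlated (``truth.correlated_pairs``, which includes the correlations
    induced by trend sharing).
    """
    planted = set(
        zip(*truth.true_edges.loc[truth.true_edges["layer"] == layer,
                                  ["source", "target"]].T.to_numpy()))
    cp = truth.correlated_pairs
    truly = set(zip(*cp.loc[cp["layer"] == layer,
                            ["source", "target"]].T.to_numpy())) | planted
    called = edges[edges["layer"] == layer] if "layer" in edges.columns else edges
    called_pairs = set(zip(called["source"], called["target"]))
    tp_planted = len(called_pairs & planted)
    sens = tp_planted / len(planted) if planted else np.nan
    n_false = len(called_pairs - truly)
    fdr = n_false / len(called_pairs) if called_pairs else 0.0
    return {"sensitivity": sens, "fdr": fdr,
            "n_true": len(planted), "n_called": len(called_pairs)}


def dmr_recovery(dmrs: pd.DataFrame, true_dmrs: pd.DataFrame,
                 ambiguous_regions: pd.DataFrame | None = None) -> dict[str, float]:
    """Sensitivity / empirical FDR of called DMRs against planted intervals.

    A true DMR is recovered iff a called DMR of the same context and delta
    sign overlaps it; a called DMR is a false positive iff it overlaps no
    true DMR of its context. Calls overlapping ``ambiguous_regions``
    (intervals carrying a planted sub-threshold methylation shift, e.g.
    expression-coupled promoters) are excluded from false-positive
    accounting: they are neither planted DMRs nor exchangeable nulls.
    """
    if ambiguous_regions is not None and len(dmrs) and len(ambiguous_regions):
        drop = np.zeros(len(dmrs), dtype=bool)
        for chrom, amb in ambiguous_regions.groupby("chrom"):
            on = (dmrs["chrom"] == chrom).to_numpy().nonzero()[0]
            if on.size == 0:
                continue
            a_idx, _ = overlap_interval_pairs(
                dmrs["start"].to_numpy()[on], dmrs["end"].to_numpy()[on],
                amb["start"].to_numpy(), amb["end"].to_numpy())
            drop[on[np.unique(a_idx)]] = True
        # keep calls that also overlap a true island (they count as signal)
        if len(true_dmrs):
            keep_true = np.zeros(len(dmrs), dtype=bool)
            for chrom, t_sub in true_dmrs.groupby("chrom"):
                on = (dmrs["chrom"] == chrom).to_numpy().nonzero()[0]
                if on.size == 0:
                    continue
                a_idx, _ = overlap_interval_pairs(
                    dmrs["start"].to_numpy()[on], dmrs["end"].to_numpy()[on],
                    t_sub["start"].to_numpy(), t_sub["end"].to_numpy())
                keep_true[on[np.unique(a_idx)]] = True
            drop &= ~keep_true
        dmrs = dmrs[~drop].reset_index(drop=True)
    if true_dmrs.empty:
        return {"sensitivity": np.nan, "fdr": 0.0 if dmrs.empty else 1.0,
                "n_true": 0, "n_called": len(dmrs)}
    recovered = np.zeros(len(true_dmrs), dtype=bool)
    called_true = np.zeros(len(dmrs), dtype=bool)
    for (chrom, context), t_sub in true_dmrs.groupby(["chrom", "context"]):
        c_sub = dmrs[(dmrs["chrom"] == chrom) & (dmrs["context"] == context)]
        if c_sub.empty:
            continue
        t_idx, c_idx = overlap_interval_pairs(
            t_sub["start"].to_numpy(), t_sub["end"].to_numpy(),
            c_sub["start"].to_numpy(), c_sub["end"].to_numpy())
        for ti, ci in zip(t_idx, c_idx):
            t_row = t_sub.iloc[ti]
            c_row = c_sub.iloc[ci]
            called_true[dmrs.index.get_loc(c_sub.index[ci])] = True
            sign_ok = (c_row["delta"] > 0) == (t_row["direction"] == "+")
            if sign_ok:
                recovered[true_dmrs.index.get_loc(t_sub.index[ti])] = True
    sens = recovered.mean() if len(recovered) else np.nan
    fdr = 1.0 - called_true.mean() if len(dmrs) else 0.0
    return {"sensitivity": float(sens), "fdr": float(fdr),
            "n_true": len(true_dmrs), "n_called": len(dmrs)}


def cluster_recovery(assignments: pd.DataFrame, trend_of: pd.Series) -> dict[str, float]:
    """Adjusted Rand index and label accuracy vs planted archetypes."""
    from sklearn.metrics import adjusted_rand_score

    merged = assignments.set_index("feature_id").join(
        trend_of.rename("true_label"), how="inner").dropna()
    if merged.empty:
        return {"ari": np.nan, "label_accuracy": np.nan, "n": 0}
    ari = adjusted_rand_score(merged["true_label"], merged["cluster_label"])
    acc = float((merged["true_label"] == merged["cluster_label"]).mean())
    return {"ari": float(ari), "label_accuracy": acc, "n": len(merged)}


def coupling_sign_recovery(meth_edges: pd.DataFrame,
                           coupled_promoters: pd.Series) -> dict[str, float]:
    """Fraction of planted promoter-expression couplings detected with the
    correct sign (methylation-expression edges, q-gated)."""
    if coupled_promoters.empty:
        return {"sign_recovery": np.nan, "n_planted": 0}
    detected = meth_edges.set_index("target")["sign"] if len(meth_edges) else \
        pd.Series(dtype=object)
    hits = 0
    for gene, sign in coupled_promoters.items():
        if gene in detected.index and detected.loc[gene] == sign:
            hits += 1
    return {"sign_recovery": hits / len(coupled_promoters),
            "n_planted": int(len(coupled_promoters))}


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Everything :func:`run_pipeline` needs, loadable from YAML."""

    mode: str = "synthetic"            # "synthetic" | "real"
    seed: int = 0
    simulation: SimulationConfig | None = None
    design: StageDesign = field(default_factory=StageDesign)
    # thresholds
    fc_threshold: float = 2.0
    q_threshold: float = 0.05
    r_threshold: float = 0.85
    fdr_method: str = "bh"
    pseudocount: float = 1.0
    # clustering
    cluster_k: int = 8
    cluster_method: str = "kmeans"
    # methylation
    promoter_bp: int = 2000
    dmr_window_bp: int = 100
    dmr_step_bp: int = 50
    dmr_min_sites: int = 4
    dmr_delta_min: float = 0.1
    dmr_min_windows: int = 2
    dmr_stage_pairs: list | None = None  # default: the mid-series adjacent pair
    metagene_body_bins: int = 40
    metagene_flank_bp: int = 2000
    metagene_flank_bin_bp: int = 100
    # real-mode inputs
    paths: dict = field(default_factory=dict)
    total_clean_reads: int = 2_000_000
    # outputs
    network_format: str = "graphml"
    write_inputs: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed, design=self.design)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = StageDesign(**raw.pop("design")) if "design" in raw else StageDesign()
        sim = None
        if "simulation" in raw:
            sim = SimulationConfig(design=design, **raw.pop("simulation"))
        pairs = raw.pop("dmr_stage_pairs", None)
        if pairs is not None:
            pairs = [tuple(p) for p in pairs]
        return cls(design=design, simulation=sim, dmr_stage_pairs=pairs, **raw)

    def default_dmr_pairs(self) -> list[tuple[str, str]]:
        if self.dmr_stage_pairs:
            return [tuple(p) for p in self.dmr_stage_pairs]
        mid = self.design.n_stages // 2
        return [(self.design.stages[mid - 1], self.design.stages[mid])]


def _load_real_inputs(config: PipelineConfig):
    paths = config.paths
    required = ["metabolome", "proteome", "transcriptome", "genes"]
    for key in required:
        if key not in paths:
            raise InputError(f"real mode requires input path {key!r}")
        if not Path(paths[key]).exists():
            raise InputError(f"missing input: {paths[key]}")
    design = config.design
    metabolome = read_stage_table(paths["metabolome"], "metabolome", design)
    proteome = read_stage_table(paths["proteome"], "proteome", design)
    transcriptome = read_stage_table(paths["transcriptome"], "transcriptome", design)
    genes = read_gene_annotation(paths["genes"])
    methylome = None
    if "cytosine_reports" in paths:
        reports = {}
        for key, p in paths["cytosine_reports"].items():
            stage, _, rep = key.rpartition("_R")
            reports[(stage, int(rep))] = p
        methylome = Methylome.from_reports(reports, design)
    sirna = read_sirna_clusters(paths["sirna"], design) if "sirna" in paths else None
    mapping = pd.Series(dtype=object)
    if "protein_to_gene" in paths:
        mp = pd.read_csv(paths["protein_to_gene"], sep="\t")
        mapping = mp.set_index(mp.columns[0])[mp.columns[1]]
    else:
        # convention: protein ids are "pr.<gene_id>"
        mapping = pd.Series({p: p[3:] for p in proteome.feature_ids
                             if str(p).startswith("pr.")})
    totals = {sid: config.total_clean_reads for sid in design.sample_ids()}
    return metabolome, proteome, transcriptome, genes, methylome, sirna, \
        mapping, totals


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis; returns the manifest (also written as JSON).

    On failure all partial outputs are removed before the exception is
    re-raised.
    """
    out_dir = Path(out_dir)
    created_dir = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run_pipeline(config, out_dir)
    except Exception:
        if created_dir:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise


def _write(df: pd.DataFrame, path: Path, outputs: dict, index: bool = False,
           index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=FLOAT_FORMAT)
    outputs[path.name] = {"path": path.name, "n_records": int(len(df))}


def _run_pipeline(config: PipelineConfig, out_dir: Path) -> dict:
    t0 = time.monotonic()
    design = config.design
    outputs: dict[str, dict] = {}
    truth = None
    dataset: SimulatedDataset | None = None

    def tick(stage_name: str) -> None:
        log.info("[%7.2fs] %s", time.monotonic() - t0, stage_name)

    if config.mode == "synthetic":
        dataset = simulate_multiomics(config.simulation)
        metabolome, proteome, transcriptome = (
            dataset.metabolome, dataset.proteome, dataset.transcriptome)
        genes, methylome, sirna = dataset.genes, dataset.methylome, dataset.sirna
        protein_to_gene, totals = dataset.protein_to_gene, dataset.total_clean_reads
        truth = dataset.truth
        if config.write_inputs:
            from .simulate import write_dataset

            write_dataset(dataset, out_dir / "inputs")
        input_hashes = {"simulation_config": _config_hash(config.simulation)}
        tick("simulated dataset")
    else:
        metabolome, proteome, transcriptome, genes, methylome, sirna, \
            protein_to_gene, totals = _load_real_inputs(config)
        input_hashes = {k: _file_hash(v) for k, v in config.paths.items()
                        if isinstance(v, str) and Path(v).exists()}
        tick("loaded inputs")

    # --- differential ------------------------------------------------------
    diff = {}
    for table in (metabolome, proteome, transcriptome):
        rec = differential_all_pairs(
            table, fc_threshold=config.fc_threshold,
            q_threshold=config.q_threshold, pseudocount=config.pseudocount,
            fdr_method=config.fdr_method)
        diff[table.layer] = rec
        _write(rec, out_dir / f"differential_{table.layer}.tsv", outputs)
    dams = differential_features(diff["metabolome"])
    deps = differential_features(diff["proteome"])
    degs = differential_features(diff["transcriptome"])
    tick(f"differential: {len(dams)} DAMs, {len(deps)} DEPs, {len(degs)} DEGs")

    # --- trends -------------------------------------------------------------
    met_means = metabolome.stage_means()
    clusters = pd.DataFrame(columns=["feature_id", "cluster_label",
                                     "centroid_distance"])
    if len(dams) >= config.cluster_k:
        clusters = cluster_dam_trends(met_means, dams, seed=config.seed,
                                      k=config.cluster_k,
                                      method=config.cluster_method)
    else:
        log.warning("only %d DAMs: skipping trend clustering", len(dams))
    _write(clusters, out_dir / "clusters.tsv", outputs)
    tick("trend clustering")

    # --- methylation ---------------------------------------------------------
    dmrs = pd.DataFrame()
    promoter_flags = pd.DataFrame(columns=["CG", "CHG", "CHH", "any"])
    meth_expr_edges = pd.DataFrame()
    genome_edges = pd.DataFrame()
    cluster_signs = pd.DataFrame()
    sirna_rpm = pd.DataFrame()
    promoter_levels = None
    if methylome is not None:
        glob = pd.DataFrame({
            ctx: stage_level_series(methylome, ctx)
            for ctx in ("CG", "CHG", "CHH")})
        glob["C"] = stage_level_series(methylome, None)
        glob.index.name = "stage"
        _write(glob, out_dir / "global_methylation.tsv", outputs, index=True)

        profile = metagene_profile(
            methylome, genes, n_body_bins=config.metagene_body_bins,
            flank_bp=config.metagene_flank_bp,
            flank_bin_bp=config.metagene_flank_bin_bp)
        _write(profile, out_dir / "metagene_profile.tsv", outputs)
        tick("methylation levels + metagene profile")

        dmr_frames = []
        for a, b in config.default_dmr_pairs():
            dmr_frames.append(call_dmrs(
                methylome, a, b, window_bp=config.dmr_window_bp,
                step_bp=config.dmr_step_bp, min_sites=config.dmr_min_sites,
                delta_min=config.dmr_delta_min,
                q_threshold=config.q_threshold,
                min_windows=config.dmr_min_windows))
        dmrs = pd.concat(dmr_frames, ignore_index=True) if dmr_frames else \
            pd.DataFrame()
        _write(dmrs, out_dir / "dmrs.tsv", outputs)
        _write_dmr_bed(dmrs, out_dir / "dmrs.bed", outputs)
        tick(f"DMR calling: {len(dmrs)} DMRs")

        _mapping, promoter_flags = promoter_dmr_genes(
            dmrs, genes, upstream_bp=config.promoter_bp)
        _write(promoter_flags, out_dir / "promoter_dmr_flags.tsv", outputs,
               index=True, index_label="gene_id")

        if sirna is not None and len(dmrs):
            sirna_rpm = sirna_rpm_in_regions(
                sirna, dmrs[["chrom", "start", "end"]], totals)
            sirna_rpm.insert(0, "chrom", dmrs["chrom"].to_numpy())
            sirna_rpm.insert(1, "start", dmrs["start"].to_numpy())
            sirna_rpm.insert(2, "end", dmrs["end"].to_numpy())
        _write(sirna_rpm, out_dir / "sirna_dmr_rpm.tsv", outputs)

        promoter_levels = promoter_level_matrix(
            methylome, genes, upstream_bp=config.promoter_bp)
        tick("promoter methylation levels")

    # --- association ---------------------------------------------------------
    tr_means = transcriptome.stage_means()
    pr_means = proteome.stage_means()
    tr_edges = build_association_edges(
        tr_means, met_means, "transcript-metabolite",
        feature_ids=degs, metabolite_ids=dams,
        r_threshold=config.r_threshold, q_threshold=config.q_threshold)
    pr_edges = build_association_edges(
        pr_means, met_means, "protein-metabolite",
        feature_ids=deps, metabolite_ids=dams,
        r_threshold=config.r_threshold, q_threshold=config.q_threshold)
    _write(tr_edges, out_dir / "edges_transcript.tsv", outputs)
    _write(pr_edges, out_dir / "edges_protein.tsv", outputs)
    database = consistency_filter(tr_edges, pr_edges, protein_to_gene,
                                  metabolite_clusters=clusters,
                                  class_of=metabolome.class_of)
    _write(database.edges, out_dir / "database_edges.tsv", outputs)
    _write(database.removed_pairs, out_dir / "removed_pairs.tsv", outputs)
    tick(f"association: {len(tr_edges)} transcript edges, "
         f"{len(pr_edges)} protein edges, {len(database.removed_pairs)} removed")

    if promoter_levels is not None:
        meth_expr_edges = methylation_expression_edges(
            promoter_levels.loc[promoter_levels.index.intersection(
                pd.Index(sorted(degs)))],
            tr_means, q_threshold=config.q_threshold)
        _write(meth_expr_edges, out_dir / "methylation_expression_edges.tsv",
               outputs)
        dam_means = met_means.loc[met_means.index.intersection(
            pd.Index(sorted(dams)))]
        genome_edges, cluster_signs = genome_methylation_dam_correlation(
            stage_level_series(methylome, None), dam_means,
            clusters if len(clusters) else None)
        _write(genome_edges, out_dir / "genome_methylation_dam.tsv", outputs)
        _write(cluster_signs, out_dir / "cluster_sign_summary.tsv", outputs)
        tick("methylation couplings")

    # --- transitions ---------------------------------------------------------
    increases = next_stage_increases(diff["metabolome"], design)
    class_table = class_transition_table(increases, metabolome.class_of, design)
    _write(class_table, out_dir / "class_transition_table.tsv", outputs,
           index=True)
    summary, _sets = transition_correlated_degs(
        increases, database, diff["transcriptome"], promoter_flags, design)
    _write(summary, out_dir / "transitions_summary.tsv", outputs)
    tick("transitions")

    # --- exports -------------------------------------------------------------
    if len(clusters):
        net_paths = export_network(database, out_dir / "networks",
                                   group_by="cluster", fmt=config.network_format)
        for name, p in net_paths.items():
            outputs[f"network:{name}"] = {
                "path": str(Path(p).relative_to(out_dir)), "n_records": None}
    chrom_counts = chromosome_class_counts(database, genes)
    _write(chrom_counts, out_dir / "chromosome_class_counts.tsv", outputs,
           index=True)

    # --- recovery ------------------------------------------------------------
    recovery: dict[str, float] = {}
    if truth is not None:
        er = edge_recovery(tr_edges, truth)
        recovery.update({f"edge_{k}": v for k, v in er.items()})
        if len(dmrs):
            from .io import promoter_table

            coupled_proms = None
            if len(truth.coupled_promoters):
                proms = promoter_table(genes, config.promoter_bp)
                coupled_proms = proms.loc[
                    proms.index.intersection(truth.coupled_promoters.index)
                ].reset_index()
            dr = dmr_recovery(dmrs, truth.true_dmrs,
                              ambiguous_regions=coupled_proms)
            recovery.update({f"dmr_{k}": v for k, v in dr.items()})
        cr = cluster_recovery(clusters, truth.trend_of) if len(clusters) else {}
        recovery.update({f"cluster_{k}": v for k, v in cr.items()})
        sr = coupling_sign_recovery(meth_expr_edges, truth.coupled_promoters)
        recovery.update({f"coupling_{k}": v for k, v in sr.items()})
        rec_df = pd.DataFrame(sorted(recovery.items()),
                              columns=["metric", "value"])
        _write(rec_df, out_dir / "recovery.tsv", outputs)
        tick("recovery report")

    manifest = {
        "software": "stageomics",
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "config": _config_dict(config),
        "input_hashes": input_hashes,
        "outputs": outputs,
        "recovery": recovery,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    tick("done")
    return manifest


def _write_dmr_bed(dmrs: pd.DataFrame, path: Path, outputs: dict) -> None:
    """DMRs as BED6: name=context:stage_a-stage_b, score=-log10 q, strand '.'"""
    with open(path, "w") as fh:
        for rec in dmrs.itertuples(index=False):
            q = max(rec.q_value, 1e-300)
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t"
                     f"{rec.context}:{rec.stage_a}-{rec.stage_b}\t"
                     f"{-np.log10(q):.4f}\t.\n")
    outputs[path.name] = {"path": path.name, "n_records": int(len(dmrs))}


def _config_dict(config) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        return obj

    return convert(config)


def _config_hash(config) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
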