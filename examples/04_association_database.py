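"""Build the gene-metabolite association database.

Cross-layer Pearson edges on 11-point stage means (|r| > 0.85, BH FDR < 0.05)
restricted to differential features, then the transcript/translation
consistency filter: a gene whose transcript and protein disagree in
correlation sign with the same metabolite is dropped as unreliable.
"""

import stageomics as so

dataset = so.simulate_multiomics(so.SimulationConfig(
    seed=0, n_metabolites=120, n_genes=600, n_proteins=240,
    n_planted_edges=80, n_planted_dmrs=20, n_coupled_promoters=20))

dams = so.differential_features(so.differential_all_pairs(dataset.metabolome))
degs = so.differential_features(so.differential_all_pairs(dataset.transcriptome))
deps = so.differential_features(so.differential_all_pairs(dataset.proteome))

met_means = dataset.metabolome.stage_means()
tr_edges = so.build_association_edges(
    dataset.transcriptome.stage_means(), met_means, "transcript-metabolite",
    feature_ids=degs, metabolite_ids=dams)
pr_edges = so.build_association_edges(
    dataset.proteome.stage_means(), met_means, "protein-metabolite",
    feature_ids=deps, metabolite_ids=dams)
db = so.consistency_filter(tr_edges, pr_edges, dataset.protein_to_gene)

print(f"transcript-metabolite edges: {len(tr_edges)}")
print(f"protein-metabolite edges:    {len(pr_edges)}")
print(f"pairs removed by the consistency filter: {len(db.removed_pairs)}")
print(f"database edges after filtering:          {len(db.edges)}")

truth = dataset.truth
rec = so.edge_recovery(tr_edges, truth)
print(f"planted-coupling sensitivity: {rec['sensitivity']:.3f}, "
      f"empirical FDR: {rec['fdr']:.3f}")
disc = truth.discordant_genes
print(f"sign-discordant genes planted: {len(disc)}, "
      f"removed pairs touching them: "
      f"{(db.removed_pairs['gene'].isin(disc)).sum()}")
# Sensitivity counts the explicitly planted couplings; the FDR counts edges
# whose underlying mean series are not truly correlated.
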