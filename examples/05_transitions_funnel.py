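"""Adjacent-stage transition accounting and the correlated-DEG funnel.

For each of the 10 adjacent stage pairs: which metabolites rise at the next
stage, their class composition, which database genes correlate with them,
which of those are DEGs for the same pair, and which of those carry a
promoter DMR.
"""

import stageomics as so

config = so.PipelineConfig(seed=0, simulation=so.SimulationConfig(
    seed=0, n_metabolites=120, n_genes=600, n_proteins=240,
    n_planted_edges=80, n_planted_dmrs=20, n_coupled_promoters=20,
    sirna_background_clusters=40))
manifest = so.run_pipeline(config, "example_run")

import pandas as pd

summary = pd.read_csv("example_run/transitions_summary.tsv", sep="\t")
print(summary.to_string(index=False))

table = pd.read_csv("example_run/class_transition_table.tsv", sep="\t",
                    index_col=0)
print(f"\nclass x transition matrix: {table.shape[0]} classes x "
      f"{table.shape[1]} transitions; grand total "
      f"{int(table.to_numpy().sum())} increased metabolites")
# Every row of the summary satisfies the funnel ordering:
# DMR-modified correlated DEGs <= correlated DEGs <= DEGs of the pair.
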