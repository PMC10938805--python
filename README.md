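# stageomics

Stage-series multi-omics integration for developmental time courses:
differential calling between developmental stages, metabolite trend
clustering, gene–metabolite association networks with a
transcript/translation consistency filter, whole-genome bisulfite
methylation analysis (region levels, metagene profiles, DMR calling,
promoter coupling, 24-nt siRNA abundance), and adjacent-stage transition
accounting — together with a synthetic multi-omics generator that plants
known structure so the whole pipeline can be validated end to end.

The package is aimed at analyses of the kind performed on fleshy-fruit
development: a metabolome, proteome, transcriptome and DNA methylome
profiled over an ordered series of stages (default S1..S11, three
biological replicates), where the questions are *which* molecules change,
*how* their trajectories group, *which* genes plausibly drive which
metabolites, and whether promoter DNA methylation tracks those genes.

## Methods at a glance

- **Differential calling** (DAM/DEP/DEG): for every stage pair (55 for 11
  stages), Welch's *t* on log2(x + 1) across replicates; a feature is
  significant iff |log2 FC| ≥ 1 on the raw stage means **and** the
  Benjamini–Hochberg *q* < 0.05, with the FDR family being all features of
  one layer in one pair. A feature is a DAM/DEP/DEG if significant in ≥ 1
  pair.
- **Trend clustering**: DAM stage-mean series are log2-transformed and
  z-scored, k-means (k = 8, 20 restarts, fixed seed) clusters them, and
  each centroid is matched one-to-one to an archetypal shape, so the labels
  I–VIII always carry the same meaning (I/II/IV early-high and declining,
  VIII and VII peaking mid-series, III/V/VI rising toward the final stages).
- **Association database**: Pearson *r* on the 11-point stage means between
  differential features and DAMs; edges kept at |r| > 0.85 and BH *q* <
  0.05 (two-sided *p* via the *t* transform with n − 2 df). A gene whose
  transcript-level and protein-level correlations with the same metabolite
  disagree in sign is removed as unreliable (the consistency filter).
- **Methylation**: weighted (count-pooled) levels per region and context
  (CG/CHG/CHH); metagene profiles over scaled gene bodies ± 2 kb flanks;
  DMRs from 100-bp windows (step 50) via Fisher's exact test on
  replicate-pooled counts + BH + a |Δ| ≥ 0.1 gate, merged and required to
  be supported by ≥ 2 consecutive significant windows; promoters are
  strand-aware 2-kb windows upstream of the 5′ end; siRNA cluster abundance
  is reads-per-million of total clean reads, assigned by cluster midpoint.
- **Transitions**: per adjacent stage pair, the metabolites increased at
  the later stage, their class × transition count matrix, and the funnel
  *correlated genes → correlated DEGs → DMR-modified correlated DEGs*.

## Worked example

```python
import stageomics as so

manifest = so.run_pipeline(so.PipelineConfig(seed=1), "run_out")
for key, value in manifest["recovery"].items():
    print(key, value)
```

This simulates the default synthetic study (300 metabolites, 5,000 genes,
1,500 proteins, 11 stages × 3 replicates, 200 planted gene–metabolite
couplings at ρ ≈ 0.97, 100 planted promoter DMRs at Δ = 0.3, depth 30×) and
runs every stage of the analysis. With seed 1 it prints, among others:

```
edge_sensitivity 1.0
edge_fdr 0.0349...
dmr_sensitivity 1.0
dmr_fdr 0.0
cluster_ari 1.0
coupling_sign_recovery 1.0
```

meaning: every planted gene–metabolite coupling survived the correlation
gates and ~3.5 % of retained edges were not truly correlated pairs; all 100
planted promoter DMRs were recovered with no false calls outside truly
shifted regions; the eight planted trend archetypes were recovered exactly
(adjusted Rand index 1.0); and the sign of every planted
promoter-methylation/expression coupling was identified correctly. The run
directory holds the full outputs as TSV/BED/GraphML plus `manifest.json`
and `recovery.tsv`.

The same run from a shell:

```bash
stageomics run-all --seed 1 --out-dir run_out
stageomics simulate --seed 1 --out-dir sim_out   # just the dataset + truth
```

`examples/` contains one short script per capability (simulation +
differential calling, trend clusters, methylation/DMRs/siRNA, the
association database, the transition funnel, and the full pipeline).

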