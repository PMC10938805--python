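# Methods

This note documents the statistical procedures, the synthetic-data model,
the defaults and the design decisions behind `stageomics`. Everything here
is implemented and exercised by the test suite; no empirical claim is made
beyond what the tests and `scripts/acceptance.py` compute.

## Study design and data model

All analyses assume an ordered developmental series (default stages
S1..S11) with a fixed number of biological replicates per stage (default
3). Internally all genomic coordinates are 0-based, half-open; cytosine
reports are read in the Bismark cytosine-report dialect (1-based) and
converted on ingest; BED input/output stays 0-based. Zero-coverage cytosine
sites are retained in the data model but excluded from every level
computation: an uncovered region has an *undefined* level (NaN), never 0.

## Differential calling

For each unordered stage pair, each feature is tested with Welch's two-sample
*t* on log2(x + c) across replicates (pseudocount c = 1 on the layer's
abundance scale, configurable). The fold-change gate uses the raw stage
means: log2 FC = log2(mean_b + c) − log2(mean_a + c). A record is
significant iff |log2 FC| ≥ log2(2) and BH *q* < 0.05. Choices:

- **One engine for all three layers.** Count-specific machinery (edgeR-style
  dispersion shrinkage) is deliberately not reimplemented; the fold-change
  and FDR gates are the operative criteria and are identical across layers.
  DEG lists from a count-model engine would differ in marginal cases.
- **FDR family** = all features of one layer within one stage pair — the
  smallest defensible family; Benjamini–Yekutieli is available via
  `fdr_method="by"`.
- Features that are all-zero in both stages are excluded (logged), constant
  non-zero features get p = 1, and a zero-variance difference gets p = 0 by
  convention (infinite *t*).
- At these conditions (3 replicates, log2-scale noise ≈ 0.3) the power of a
  single pair-wise Welch test for a 4× shift is ≈ 0.8 after BH; a feature
  with a genuine developmental shift is nevertheless recovered as
  differential with near-certainty because all 55 pairs are tested and one
  significant pair suffices — that is the operative definition of a
  DAM/DEP/DEG here.

## Trend clustering

DAM stage-mean series are log2(x + 1)-transformed (standard for intensity
data; it symmetrises the multiplicative noise) and z-scored with sample sd
(ddof = 1); a constant series maps to the zero vector and is flagged
degenerate. k-means (k = 8, Euclidean, `n_init` = 20, fixed seed) runs on a
canonical (sorted-id) row order so results are invariant to input order;
Ward agglomeration is available as an alternative. Cluster labels are
anchored to eight archetypal z-shapes by solving an optimal one-to-one
assignment on correlation distance (Hungarian algorithm) — a greedy
nearest-archetype map could assign two centroids the same label, and the
label map is required to be a bijection. The archetypes: I linear decline,
II fast early decay, IV plateau-then-late-decline (the early-high family);
VIII and VII Gaussian peaks at ~50 % and ~60 % of the series (S6, S7 for 11
stages); III linear rise, VI saturating early rise, V late exponential rise
(the late-high family).

## Association database

Edges are Pearson correlations of the per-stage replicate means (11 points)
on the raw abundance scale — Pearson is scale-invariant, so this matches
either a raw or a normalised reading of the data. Two-sided *p*-values come
from the *t* transform with n − 2 df; BH runs across all tested pairs of a
layer; retained edges satisfy |r| > 0.85 and *q* < 0.05. Tested pairs are
restricted to differential features (DEGs/DEPs × DAMs). Zero-variance
series are excluded rather than scored.

The **consistency filter** removes a (gene, metabolite) pair when the gene's
transcript edge and its protein edge to that metabolite disagree in sign
(sign discordance only; magnitude differences are not penalised, since
transcript and protein dynamic ranges differ systematically). Genes without
a detected protein pass through untouched.

**Methylation couplings.** Per gene, the promoter methylation series is the
count-pooled level over all contexts and promoter sites per stage; genes
with an undefined level in any stage are skipped (logged). The correlation
with the gene's expression stage means is reported in both signs with a
*q* gate only. The genome-wide series (all contexts pooled) is correlated
against every DAM and summarised as the median *r* per trend cluster.

## Methylation analysis

- **Region level** = Σ meth / Σ (meth + unmeth) over covered sites of the
  requested context inside the interval (weighted/pooled level). Pooling
  across replicates or stages is a count sum, so levels over a union of
  disjoint intervals equal the count-pooled level of the parts.
- **Metagene profile**: gene bodies are rescaled to 40 bins, flanks are
  fixed 100-bp bins over ±2 kb, minus-strand genes are mirrored so bin 0 is
  always the far 5′ end; each bin's level pools all genes' site counts.
- **DMR calling** replaces a smoothed beta-binomial engine with a
  self-contained, oracle-testable procedure: per context, 100-bp windows at
  50-bp steps over replicate-pooled counts; Fisher's exact test on the 2×2
  (meth/unmeth × stage) table; BH across all tested windows of the context;
  gates: ≥ 4 sites per window, *q* < 0.05, |Δ level| ≥ 0.1. Significant
  windows of the same context and delta sign that overlap or lie within one
  step are merged; merged levels are recomputed from pooled counts and the
  delta gate is re-applied to the merged estimate. A reported DMR must be
  supported by **≥ 2 consecutive significant windows** (`min_windows`,
  configurable): at ~30× depth a lone window holding only the minimum site
  count is dominated by sampling noise, and overlapping windows give one
  fluctuation several chances to pass the gates; the consistency rule
  removes those single-window artefacts without costing sensitivity on real
  regions, which span several windows.
- **Promoters** are strand-aware fixed windows (default 2 kb) immediately
  upstream of the annotated 5′ end, clipped at contig boundaries; the
  length is a config knob. Promoter–DMR overlap means ≥ 1 shared base.
- **siRNA abundance**: RPM = 1e6 × (Σ reads of clusters whose midpoint lies
  in the region) / total clean reads; the midpoint rule avoids double
  counting across adjacent regions.
- Symmetric CG sites are kept per strand (not collapsed), matching the
  per-cytosine report granularity.

## Synthetic data generator

The generator emulates the study conditions end to end; its defaults are
the package's reference conditions.

| knob | default | meaning |
| --- | --- | --- |
| `n_metabolites` / `n_genes` / `n_proteins` | 300 / 5000 / 1500 | feature counts |
| `frac_dam` | 0.8 | fraction of metabolites given a trend archetype |
| `log2_amplitude` | 1.0 | trend amplitude on log2 scale (≈ 6–10× dynamic range) |
| `noise_sd` | 0.3 | replicate noise sd, log2 scale (≈ 23 % CV) |
| `n_planted_edges`, `edge_rho` | 200, 0.97 | gene↔metabolite couplings and their |r| |
| `frac_negative_edges` | 0.36 | sign mix of couplings (matching the ~64:36 positive:negative ratio typical of such datasets) |
| `nb_dispersion` | 0.1 | NB dispersion of the sequencing-count emission |
| `discordant_frac` | 0.1 | planted proteins with sign-flipped trends |
| `meth_sites_per_promoter` | 20 per context | 14 in a 200-bp dense island + 6 scattered |
| `depth` | 30 | mean per-cytosine read depth (Poisson) |
| `chh_start→chh_end` | 0.10→0.25 | population CHH level across stages (linear) |
| `cg_start→cg_end` | 0.55→0.45 | CG level (linear decline); CHG flat at 0.30 |
| `n_planted_dmrs`, `dmr_delta` | 100, 0.3 | promoter DMRs switching on mid-series |
| `n_coupled_promoters`, `coupling_delta` | 100, 0.05 | promoters whose level tracks expression |

Construction details that matter:

- **Metabolites**: trended metabolites follow their archetype on the log2
  scale (2^(b + A·z)); replicates carry multiplicative 2^N(0, noise_sd)
  noise. Null metabolites are flat — ground truth is exhaustive and null
  features are exchangeable.
- **Planted couplings** are anchored on the *realised* metabolite stage
  means (the partner gene responds to the metabolite series as measured):
  the gene mean series is an affine transform of the anchor achieving
  exactly ±ρ via a Gram–Schmidt residual, with the residual direction
  chosen (deterministic projected ascent) to maximise the series minimum.
  This keeps the partner expressed at all stages; a partner forced to
  anti-correlate with a sharply peaked series otherwise acquires a low
  coefficient of variation and its realised correlation is visibly
  attenuated by replicate noise. Under the defaults ≥ 95 % (measured
  ≈ 99 %) of planted edges keep |r| ≥ 0.9 on realised stage means.
- **Transcripts** are emitted twice: the analysis-facing RPKM-like
  intensity (lognormal replicate noise) and negative-binomial sequencing
  counts layered on the per-replicate abundance (dispersion 0.1).
- **Proteome** covers the planted genes plus a random subset; concordant
  proteins reuse the gene's mean series with extra replicate noise,
  discordant ones are re-coupled with the opposite sign to exercise the
  consistency filter.
- **Ground truth is exhaustive**: planting a gene on one metabolite
  necessarily correlates it with every metabolite sharing that archetype,
  so the truth records both the planted list (for sensitivity) and the
  complete set of pairs whose underlying mean series exceed the |r|
  threshold (for honest false-discovery accounting). Recovery therefore
  asks two different questions: "were the planted couplings found?" and
  "was anything retained that is not truly correlated?".
- **Methylation**: one synthetic chromosome with genes tiled every 5 kb on
  alternating strands; each promoter has, per context, 14 sites in a 200-bp
  island plus 6 scattered, 10 body sites and 6 downstream-flank sites.
  Levels are linear per stage and context; planted DMR islands shift by
  ±`dmr_delta` from the mid-series stage onward (so the default DMR
  contrast is the adjacent pair straddling that switch); coupled promoters
  add `coupling_delta` × the gene's z-scored trend to all promoter sites —
  `coupling_delta` is deliberately small enough that couplings stay below
  the DMR delta gate, keeping the two planted signals separable. Depth is
  Poisson per site/sample, methylated counts are binomial. In recovery
  scoring, calls overlapping coupled promoters are excluded from
  false-positive accounting (they are real, planted, sub-threshold shifts,
  neither planted DMRs nor exchangeable nulls).
- **siRNA clusters** sit in half of the planted DMR islands (high mean
  reads) plus scattered background clusters; totals for RPM default to
  2 × 10⁶ clean reads per sample.
- A single `numpy` Generator seeded from the config drives every draw; the
  full pipeline is byte-for-byte reproducible at a fixed seed (k-means uses
  the same seed; rows are processed in canonical order).

What the generator does **not** emulate: missing values and detection
limits in LC–MS, count-depth variation between libraries, genome-scale
sequence context (the chromosome is abstract, contexts are labels),
linkage between neighbouring genes, batch effects, and biological
covariance beyond the planted couplings. Passing tests therefore
demonstrate correctness and calibration of the procedures under a clean
generative model, not performance on real data.

## Pipeline defaults and outputs

`run_pipeline` executes simulate/load → differential (3 layers) → trend
clustering → methylation (global levels, metagene profile, DMRs for the
mid-series adjacent pair, promoter overlap, siRNA RPM) → association
(edges, consistency filter, methylation couplings) → transitions → exports
(GraphML/TSV networks per cluster, class × chromosome counts), writing TSV
outputs with a fixed float format (`%.10g`) and a JSON manifest (config
snapshot, seed, input hashes, record counts, version; no timestamps, so
reruns are byte-identical). On failure, partial outputs are removed.
Exit codes of the CLI: 0 ok, 1 input error, 2 internal error.

Default problem sizes were chosen so the full default run completes in
roughly a minute on one CPU; the dominant cost is the Fisher sweep of the
DMR caller (~50 k tested windows).

## Known limitations

- The differential engine is a Welch *t*, not a count model; very low-count
  genes are better served by dedicated RNA-seq machinery.
- The DMR caller pools replicates within stage and therefore does not model
  between-replicate dispersion; its FDR control is per-window BH plus the
  consistency rule, not a region-level error model.
- Correlation edges are marginal Pearson associations on 11 points; the
  database is a screening tool, not a causal network.
- The archetype anchoring assumes the eight reference shapes are a
  reasonable basis for the observed trends; datasets with fundamentally
  different kinetics would need a different archetype set (pass
  `archetypes=` to `cluster_trends`).
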