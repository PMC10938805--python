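"""Synthetic stage-series multi-omics generator with planted ground truth.

The generator emulates an 11-stage x 3-replicate fruit-development study:

* metabolite intensities whose stage trends follow eight archetypal shapes
  (early-high, mid-peak and late-high variants, labelled I-VIII);
* transcript abundances for a small set of genes planted as near-exact linear
  partners of metabolite trajectories (Pearson ~ ``edge_rho``), embedded in a
  large background of untrended genes, emitted both as RPKM-like intensities
  and as negative-binomial sequencing counts;
* a proteome covering a subset of genes, including a configurable fraction of
  "discordant" proteins whose trend is sign-flipped relative to their
  transcript (to exercise the transcript/translation consistency filter);
* per-cytosine binomial methylation on one synthetic chromosome with a rising
  CHH level, a falling CG level and a flat CHG level across stages, planted
  promoter DMRs that switch on mid-series, and promoter methylation series
  coupled to the expression of selected genes;
* 24-nt siRNA clusters placed in a subset of planted DMRs plus background.

Everything stochastic flows through one ``numpy`` Generator seeded from the
config, so a fixed seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import StageDesign
from .errors import InputError
from .io import (
    CONTEXTS,
    FeatureTable,
    GeneModel,
    Methylome,
    promoter_interval,
)

log = logging.getLogger(__name__)

ARCHETYPE_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

#: metabolite-class labels used by the generator (subset of classes commonly
#: reported for fleshy-fruit metabolomes)
METABOLITE_CLASSES = (
    "Amino acid", "Amino acid derivatives", "Anthocyanins", "Carbohydrates",
    "Catechin derivatives", "Coumarins", "Flavone", "Flavonol",
    "Hydroxycinnamoyl derivatives", "Lipids_Fatty acids",
    "Lipids_Glycerolipids", "Nucleotide and its derivates", "Organic acids",
    "Phytohormones", "Vitamins", "Others",
)


def make_archetypes(n_stages: int = 11) -> pd.DataFrame:
    """Eight archetypal z-scale trend shapes over ``n_stages`` stages.

    I/II/IV decline (high early), VII peaks ~60% through the series and VIII
    just before it (stages S7 and S6 of an 11-stage series), III/V/VI rise
    (high at the final stages). Each row is z-standardised (sample sd).
    """
    if n_stages < 3:
        raise InputError("n_stages must be >= 3")
    t = np.linspace(0.0, 1.0, n_stages)
    shapes = {
        "I": -t,
        "II": np.exp(-5.0 * t),
        "III": t,
        "IV": 1.0 / (1.0 + np.exp(10.0 * (t - 0.65))),
        "V": np.exp(4.0 * (t - 1.0)),
        "VI": 1.0 - np.exp(-4.0 * t),
        "VII": np.exp(-((t - 0.6) ** 2) / (2 * 0.12**2)),
        "VIII": np.exp(-((t - 0.5) ** 2) / (2 * 0.12**2)),
    }
    rows = []
    for label in ARCHETYPE_LABELS:
        x = shapes[label]
        rows.append((x - x.mean()) / x.std(ddof=1))
    return pd.DataFrame(rows, index=pd.Index(ARCHETYPE_LABELS, name="archetype"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the package's reference
    conditions (11 stages x 3 replicates, see docs/methods.md)."""

    seed: int = 0
    design: StageDesign = field(default_factory=StageDesign)
    n_metabolites: int = 300
    n_genes: int = 5000
    n_proteins: int = 1500
    frac_dam: float = 0.8              # fraction of metabolites given a trend
    n_planted_edges: int = 200         # gene<->metabolite linear couplings
    edge_rho: float = 0.97             # target |Pearson r| of planted couplings
    noise_sd: float = 0.3              # replicate noise, log2 scale
    nb_dispersion: float = 0.1         # NB dispersion of sequencing counts
    meth_sites_per_promoter: int = 20  # per context
    depth: float = 30.0                # mean read depth per cytosine
    chh_start: float = 0.10
    chh_end: float = 0.25
    cg_start: float = 0.55
    cg_end: float = 0.45
    chg_level: float = 0.30
    n_planted_dmrs: int = 100
    dmr_delta: float = 0.3             # methylation shift of planted DMRs
    # secondary knobs
    log2_amplitude: float = 1.0        # metabolite trend amplitude (log2)
    frac_negative_edges: float = 0.36  # negative:positive mix of couplings
    discordant_frac: float = 0.10      # proteins sign-flipped vs transcript
    n_coupled_promoters: int = 100     # promoters coupled to expression
    coupling_delta: float = 0.05       # methylation swing per expression sd
    island_bp: int = 200               # dense-site island width per promoter
    island_sites: int = 14             # sites (per context) inside the island
    induced_r_threshold: float = 0.85  # |r| above which a pair is truly coupled
    body_sites: int = 10               # sites per context in the gene body
    downstream_sites: int = 6          # sites per context in the 3' flank
    gene_length: int = 1500
    gene_spacing: int = 5000
    promoter_bp: int = 2000
    sirna_background_clusters: int = 200
    sirna_dmr_mean: float = 100.0      # mean cluster reads inside DMRs
    sirna_background_mean: float = 20.0
    total_clean_reads: int = 2_000_000

    def __post_init__(self) -> None:
        for name in ("frac_dam", "frac_negative_edges", "discordant_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1]")
        for name in ("chh_start", "chh_end", "cg_start", "cg_end", "chg_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be a level in [0, 1]")
        for name in ("n_metabolites", "n_genes", "n_proteins"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be positive")
        if self.n_planted_edges > self.n_genes:
            raise InputError("n_planted_edges exceeds n_genes")
        if self.n_proteins > self.n_genes:
            raise InputError("n_proteins exceeds n_genes")
        if self.n_planted_dmrs > self.n_genes:
            raise InputError("n_planted_dmrs exceeds n_genes")
        if self.island_sites > self.meth_sites_per_promoter:
            raise InputError("island_sites exceeds meth_sites_per_promoter")
        if self.gene_length + 2 * self.promoter_bp > 2 * self.gene_spacing:
            raise InputError("gene_spacing too small for gene_length + flanks")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset, for recovery scoring.

    ``true_edges`` lists the couplings that were explicitly planted;
    ``correlated_pairs`` is the exhaustive set of feature-metabolite pairs
    whose *underlying mean series* correlate beyond the association threshold
    — planting a gene on one metabolite necessarily couples it to every
    metabolite sharing that trend, and an honest false-discovery count must
    treat those induced correlations as real.
    """

    trend_of: pd.Series            # metabolite -> archetype label (NaN if null)
    true_edges: pd.DataFrame       # source, target, layer, sign (planted)
    correlated_pairs: pd.DataFrame  # source, target, layer, r_true (induced)
    true_dmrs: pd.DataFrame        # chrom, start, end, context, direction, gene_id
    coupled_promoters: pd.Series   # gene -> "+" / "-"
    discordant_genes: frozenset    # genes with sign-flipped protein trends


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    metabolome: FeatureTable
    transcriptome: FeatureTable    # RPKM-like intensities (analysis scale)
    counts: pd.DataFrame           # NB sequencing counts, genes x samples
    proteome: FeatureTable
    protein_to_gene: pd.Series
    genes: list[GeneModel]
    methylome: Methylome
    sirna: pd.DataFrame
    total_clean_reads: dict[tuple[str, int], int]
    truth: GroundTruth


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _best_residual(su: np.ndarray, rho: float, n_iter: int = 30) -> np.ndarray:
    """Unit residual orthogonal to {1, su} maximising min(rho*su + c*e).

    Keeps the coupled partner expressed at every stage (shallow dip), which
    maximises its signal-to-noise on the raw scale. Deterministic projected
    subgradient ascent on the series minimum.
    """
    resid = np.sqrt(1.0 - rho**2)
    n = su.size
    e = np.zeros(n)
    e[np.argmin(su)] = 1.0
    e -= e.mean()
    e -= (e @ su) * su
    nrm = np.linalg.norm(e)
    if nrm == 0:  # anchor is itself a single-coordinate spike
        e = np.ones(n) / np.sqrt(n)
        e -= (e @ su) * su
        nrm = np.linalg.norm(e)
        if nrm == 0:
            return np.zeros(n)
    e /= nrm
    ones = np.ones(n) / np.sqrt(n)
    for _ in range(n_iter):
        v = rho * su + resid * e
        g = np.zeros(n)
        g[np.argmin(v)] = 1.0
        g -= (g @ ones) * ones
        g -= (g @ su) * su
        e = e + 0.5 * g
        e /= np.linalg.norm(e)
    return e


def _coupled_series(anchor: np.ndarray, rho: float, sign: int,
                    base: float) -> np.ndarray:
    """Positive mean series whose Pearson r with ``anchor`` is exactly
    ``sign * rho`` (Gram-Schmidt residual, dip-minimising direction)."""
    u = anchor - anchor.mean()
    norm = np.linalg.norm(u)
    if norm == 0:
        raise InputError("cannot couple to a constant anchor series")
    u = u / norm
    su = sign * u
    e = _best_residual(su, rho)
    v = rho * su + np.sqrt(1.0 - rho**2) * e
    lo, hi = v.min(), v.max()
    return base * (v - lo + 0.02 * (hi - lo)) / (hi - lo)


def _lognormal_replicates(mean_series: np.ndarray, design: StageDesign,
                          noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Expand (n_features, n_stages) means to replicate values with
    multiplicative 2^N(0, noise_sd) replicate noise."""
    n_feat, n_stages = mean_series.shape
    n_rep = design.n_replicates
    noise = rng.normal(scale=noise_sd, size=(n_feat, n_stages, n_rep))
    values = mean_series[:, :, None] * np.exp2(noise)
    return values.reshape(n_feat, n_stages * n_rep)


def simulate_multiomics(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic dataset (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    design = config.design
    stages, n_stages = design.stages, design.n_stages
    columns = design.columns()
    archetypes = make_archetypes(n_stages)

    # ----- metabolome -----------------------------------------------------
    met_ids = [f"M{i + 1:04d}" for i in range(config.n_metabolites)]
    n_dam = int(round(config.frac_dam * config.n_metabolites))
    trended_idx = rng.choice(config.n_metabolites, size=n_dam, replace=False)
    trend_of = pd.Series(pd.NA, index=pd.Index(met_ids, name="feature_id"),
                         dtype="object")
    labels = rng.choice(ARCHETYPE_LABELS, size=n_dam)
    trend_of.iloc[trended_idx] = labels

    base_log2 = rng.uniform(6.0, 12.0, size=config.n_metabolites)
    met_means = np.exp2(base_log2)[:, None] * np.ones((1, n_stages))
    for row, label in zip(trended_idx, labels):
        z = archetypes.loc[label].to_numpy()
        met_means[row] = np.exp2(base_log2[row] + config.log2_amplitude * z)
    met_values = _lognormal_replicates(met_means, design, config.noise_sd, rng)
    classes = pd.Series(rng.choice(METABOLITE_CLASSES, size=config.n_metabolites),
                        index=met_ids, name="class")
    metabolome = FeatureTable(
        layer="metabolome",
        values=pd.DataFrame(met_values, index=pd.Index(met_ids, name="feature_id"),
                            columns=columns),
        design=design, class_of=classes,
    )
    # realised replicate-mean trajectories anchor the planted couplings:
    # partner genes respond to the metabolite series as measured
    met_hat = metabolome.stage_means().to_numpy()

    # ----- gene models ----------------------------------------------------
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    genes = []
    offset = config.promoter_bp + 500
    for i, gid in enumerate(gene_ids):
        start = i * config.gene_spacing + offset
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(gid, "ChrSim", start, start + config.gene_length, strand))

    # ----- planted gene partners + transcriptome --------------------------
    edge_genes = rng.choice(config.n_genes, size=config.n_planted_edges,
                            replace=False)
    trended_ids = [met_ids[i] for i in trended_idx]
    edge_rows = []
    gene_means = np.exp2(rng.uniform(5.0, 9.0, size=config.n_genes))[:, None] \
        * np.ones((1, n_stages))
    if config.n_planted_edges > 0 and not trended_ids:
        log.warning("no trended metabolites available; planting no edges")
        edge_genes = edge_genes[:0]
    if len(edge_genes):
        partner_idx = rng.choice(
            len(trended_ids), size=len(edge_genes),
            replace=len(edge_genes) > len(trended_ids))
        partner_pos = [met_ids.index(trended_ids[j]) for j in partner_idx]
        signs = np.where(rng.random(len(edge_genes)) < config.frac_negative_edges,
                         -1, 1)
        for g_row, m_row, sign in zip(edge_genes, partner_pos, signs):
            base = float(gene_means[g_row, 0])
            gene_means[g_row] = _coupled_series(
                met_hat[m_row], config.edge_rho, int(sign), base)
            edge_rows.append((gene_ids[g_row], met_ids[m_row],
                              "transcript-metabolite", "+" if sign > 0 else "-"))

    expr_values = _lognormal_replicates(gene_means, design, config.noise_sd, rng)
    transcriptome = FeatureTable(
        layer="transcriptome",
        values=pd.DataFrame(expr_values,
                            index=pd.Index(gene_ids, name="feature_id"),
                            columns=columns),
        design=design,
    )
    # sequencing counts: NB sampling layered on the per-replicate abundance
    disp = config.nb_dispersion
    counts = rng.negative_binomial(
        1.0 / disp, 1.0 / (1.0 + disp * expr_values))
    counts = pd.DataFrame(counts, index=pd.Index(gene_ids, name="feature_id"),
                          columns=columns)

    # ----- proteome -------------------------------------------------------
    planted_gene_ids = [gene_ids[i] for i in edge_genes]
    other_genes = [g for g in gene_ids if g not in set(planted_gene_ids)]
    n_extra = config.n_proteins - min(config.n_proteins, len(planted_gene_ids))
    covered = planted_gene_ids[:config.n_proteins] + \
        list(rng.choice(other_genes, size=n_extra, replace=False))
    protein_ids = [f"pr.{g}" for g in covered]
    protein_to_gene = pd.Series(covered, index=pd.Index(protein_ids, name="protein_id"))
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    planted_set = set(planted_gene_ids)
    edge_sign = {g: s for g, _m, _l, s in edge_rows}
    edge_partner = {g: m for g, m, _l, _s in edge_rows}

    prot_means = np.empty((len(covered), n_stages))
    discordant: set[str] = set()
    for i, g in enumerate(covered):
        if g in planted_set and rng.random() < config.discordant_frac:
            discordant.add(g)
            m_row = met_ids.index(edge_partner[g])
            sign = 1 if edge_sign[g] == "-" else -1  # flipped
            prot_means[i] = _coupled_series(
                met_hat[m_row], config.edge_rho, sign,
                float(gene_means[gene_row[g]].mean()))
        else:
            prot_means[i] = gene_means[gene_row[g]]
    prot_values = _lognormal_replicates(prot_means, design, config.noise_sd, rng)
    proteome = FeatureTable(
        layer="proteome",
        values=pd.DataFrame(prot_values,
                            index=pd.Index(protein_ids, name="feature_id"),
                            columns=columns),
        design=design,
    )
    for g in covered:
        if g in planted_set:
            sign = edge_sign[g]
            if g in discordant:
                sign = "-" if sign == "+" else "+"
            edge_rows.append((f"pr.{g}", edge_partner[g],
                              "protein-metabolite", sign))

    true_edges = pd.DataFrame(edge_rows,
                              columns=["source", "target", "layer", "sign"])

    # exhaustive induced correlations: every (trended feature, trended
    # metabolite) pair whose mean-series |r| exceeds the association threshold
    trended_rows = np.sort(trended_idx)
    correlated_pairs = _induced_pairs(
        gene_means[edge_genes] if len(edge_genes) else np.empty((0, n_stages)),
        [gene_ids[i] for i in edge_genes], "transcript-metabolite",
        met_hat[trended_rows], [met_ids[i] for i in trended_rows],
        config.induced_r_threshold)
    prot_pairs = _induced_pairs(
        prot_means, protein_ids, "protein-metabolite",
        met_hat[trended_rows], [met_ids[i] for i in trended_rows],
        config.induced_r_threshold)
    correlated_pairs = pd.concat([correlated_pairs, prot_pairs],
                                 ignore_index=True)

    # ----- methylation ----------------------------------------------------
    dmr_gene_rows = list(edge_genes[:config.n_planted_dmrs])
    if len(dmr_gene_rows) < config.n_planted_dmrs:
        pool = np.setdiff1d(np.arange(config.n_genes), edge_genes)
        extra = rng.choice(pool, size=config.n_planted_dmrs - len(dmr_gene_rows),
                           replace=False)
        dmr_gene_rows += list(extra)
    coupled_rows = list(edge_genes[config.n_planted_dmrs:
                                   config.n_planted_dmrs + config.n_coupled_promoters])
    if len(coupled_rows) < config.n_coupled_promoters:
        log.warning("only %d trended genes available for promoter coupling "
                    "(requested %d)", len(coupled_rows), config.n_coupled_promoters)

    site_chunks = []   # (pos, context_idx, gene_row, in_island)
    island_of: dict[int, tuple[int, int]] = {}
    n_scatter = config.meth_sites_per_promoter - config.island_sites
    for g_row, gene in enumerate(genes):
        _, p_start, p_end = promoter_interval(gene, config.promoter_bp)
        if gene.strand == "+":
            d_start, d_end = gene.end, gene.end + config.promoter_bp
        else:
            d_start, d_end = max(0, gene.start - config.promoter_bp), gene.start
        isl_start = int(rng.integers(p_start, max(p_start + 1, p_end - config.island_bp)))
        isl_end = isl_start + config.island_bp
        island_of[g_row] = (isl_start, isl_end)
        for c_idx in range(len(CONTEXTS)):
            pos = np.concatenate([
                rng.integers(isl_start, isl_end, size=config.island_sites),
                rng.integers(p_start, p_end, size=n_scatter),
                rng.integers(gene.start, gene.end, size=config.body_sites),
                rng.integers(d_start, d_end, size=config.downstream_sites),
            ])
            island = np.zeros(pos.size, dtype=bool)
            island[:config.island_sites] = True
            site_chunks.append((pos, c_idx, g_row, island))

    pos_all = np.concatenate([c[0] for c in site_chunks])
    ctx_all = np.concatenate([np.full(c[0].size, c[1], dtype=np.int8)
                              for c in site_chunks])
    gene_all = np.concatenate([np.full(c[0].size, c[2], dtype=np.int32)
                               for c in site_chunks])
    island_all = np.concatenate([c[3] for c in site_chunks])
    order = np.lexsort((ctx_all, pos_all))
    pos_all, ctx_all, gene_all, island_all = (
        pos_all[order], ctx_all[order], gene_all[order], island_all[order])
    n_sites = pos_all.size

    base_by_ctx = np.stack([
        np.linspace(config.cg_start, config.cg_end, n_stages),    # CG
        np.full(n_stages, config.chg_level),                      # CHG
        np.linspace(config.chh_start, config.chh_end, n_stages),  # CHH
    ])
    levels = base_by_ctx[ctx_all]                                 # sites x stages

    step_idx = n_stages // 2  # planted shifts act from this stage onward
    dmr_rows = []
    promoter_site_mask = _promoter_site_mask(pos_all, gene_all, genes,
                                             config.promoter_bp)
    for g_row in dmr_gene_rows:
        ctx = int(rng.integers(0, len(CONTEXTS)))
        direction = 1 if rng.random() < 0.5 else -1
        isl_start, isl_end = island_of[g_row]
        mask = (gene_all == g_row) & (ctx_all == ctx) & island_all
        levels[np.ix_(mask.nonzero()[0], np.arange(step_idx, n_stages))] += \
            direction * config.dmr_delta
        dmr_rows.append(("ChrSim", isl_start, isl_end, CONTEXTS[ctx],
                         "+" if direction > 0 else "-", gene_ids[g_row]))
    true_dmrs = pd.DataFrame(
        dmr_rows, columns=["chrom", "start", "end", "context", "direction",
                           "gene_id"])

    coupled = {}
    for g_row in coupled_rows:
        sign = 1 if rng.random() < 0.5 else -1
        zg = _zscore(gene_means[g_row])
        mask = (gene_all == g_row) & promoter_site_mask
        levels[mask.nonzero()[0]] += sign * config.coupling_delta * zg[None, :]
        coupled[gene_ids[g_row]] = "+" if sign > 0 else "-"
    coupled_promoters = pd.Series(coupled, dtype="object")
    coupled_promoters.index.name = "gene_id"

    np.clip(levels, 0.01, 0.99, out=levels)

    n_samples = len(design.sample_ids())
    depth = rng.poisson(config.depth, size=(n_sites, n_samples)).astype(np.int32)
    stage_col = np.repeat(np.arange(n_stages), design.n_replicates)
    meth = rng.binomial(depth, levels[:, stage_col]).astype(np.int32)
    strands = np.where(rng.random(n_sites) < 0.5, "+", "-")
    sites = pd.DataFrame({
        "chrom": "ChrSim",
        "pos": pos_all,
        "strand": strands,
        "context": np.array(CONTEXTS)[ctx_all],
    })
    methylome = Methylome(sites=sites, meth=meth, total=depth, design=design)

    # ----- 24-nt siRNA clusters -------------------------------------------
    sirna_rows = []
    n_in_dmr = len(true_dmrs) // 2
    for i in range(n_in_dmr):
        r = true_dmrs.iloc[i]
        sirna_rows.append(("ChrSim", int(r.start), int(r.end)))
    chrom_len = config.n_genes * config.gene_spacing + 2 * offset
    for _ in range(config.sirna_background_clusters):
        w = int(rng.integers(100, 500))
        s = int(rng.integers(0, chrom_len - w))
        sirna_rows.append(("ChrSim", s, s + w))
    sirna = pd.DataFrame(sirna_rows, columns=["chrom", "start", "end"])
    sirna.insert(3, "name", [f"cl{i + 1:05d}" for i in range(len(sirna))])
    means = np.where(np.arange(len(sirna)) < n_in_dmr,
                     config.sirna_dmr_mean, config.sirna_background_mean)
    cl_counts = rng.negative_binomial(
        1.0 / disp, 1.0 / (1.0 + disp * means)[:, None] * np.ones((1, n_samples)))
    for j, col in enumerate(columns):
        sirna[col] = cl_counts[:, j]
    total_clean = {sid: config.total_clean_reads for sid in design.sample_ids()}

    truth = GroundTruth(
        trend_of=trend_of,
        true_edges=true_edges,
        correlated_pairs=correlated_pairs,
        true_dmrs=true_dmrs,
        coupled_promoters=coupled_promoters,
        discordant_genes=frozenset(discordant),
    )
    return SimulatedDataset(
        config=config, metabolome=metabolome, transcriptome=transcriptome,
        counts=counts, proteome=proteome, protein_to_gene=protein_to_gene,
        genes=genes, methylome=methylome, sirna=sirna,
        total_clean_reads=total_clean, truth=truth,
    )


def _induced_pairs(feat_means: np.ndarray, feat_ids, layer: str,
                   met_series: np.ndarray, met_ids_sub,
                   r_threshold: float) -> pd.DataFrame:
    """Pairs whose underlying mean series correlate beyond the threshold."""
    cols = ["source", "target", "layer", "r_true"]
    if len(feat_ids) == 0 or len(met_ids_sub) == 0:
        return pd.DataFrame(columns=cols)

    def _std(x):
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = np.inf
        return (x - mu) / sd

    n = feat_means.shape[1]
    r = _std(feat_means) @ _std(met_series).T / (n - 1)
    fi, mi = (np.abs(r) > r_threshold).nonzero()
    return pd.DataFrame({
        "source": np.asarray(feat_ids, dtype=object)[fi],
        "target": np.asarray(met_ids_sub, dtype=object)[mi],
        "layer": layer,
        "r_true": r[fi, mi],
    })


def _promoter_site_mask(pos: np.ndarray, gene_row: np.ndarray,
                        genes: list[GeneModel], promoter_bp: int) -> np.ndarray:
    """True for sites lying inside the promoter of their own gene."""
    starts = np.empty(len(genes), dtype=np.int64)
    ends = np.empty(len(genes), dtype=np.int64)
    for i, g in enumerate(genes):
        _, s, e = promoter_interval(g, promoter_bp)
        starts[i], ends[i] = s, e
    return (pos >= starts[gene_row]) & (pos < ends[gene_row])


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict[str, str]:
    """Write all layers in their standard on-disk formats plus the
    ground-truth bundle; returns {name: path}."""
    from pathlib import Path

    from .io import (write_gene_annotation, write_sirna_clusters,
                     write_stage_table)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for name, table in (("metabolome", dataset.metabolome),
                        ("proteome", dataset.proteome),
                        ("transcriptome", dataset.transcriptome)):
        p = out / f"{name}.tsv"
        write_stage_table(table, p)
        paths[name] = str(p)
    p = out / "transcriptome_counts.tsv"
    dataset.counts.to_csv(p, sep="\t", index_label="feature_id")
    paths["transcriptome_counts"] = str(p)
    p = out / "genes.bed"
    write_gene_annotation(dataset.genes, p)
    paths["genes"] = str(p)
    p = out / "sirna_clusters.tsv"
    write_sirna_clusters(dataset.sirna, p)
    paths["sirna_clusters"] = str(p)
    for rp in dataset.methylome.to_reports(out / "cytosine_reports"):
        paths[f"cytosine:{Path(rp).name}"] = rp
    truth_dir = out / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    t = dataset.truth
    t.trend_of.to_csv(truth_dir / "trend_of.tsv", sep="\t", header=["archetype"])
    t.true_edges.to_csv(truth_dir / "true_edges.tsv", sep="\t", index=False)
    t.correlated_pairs.to_csv(truth_dir / "correlated_pairs.tsv", sep="\t",
                              index=False)
    t.true_dmrs.to_csv(truth_dir / "true_dmrs.tsv", sep="\t", index=False)
    t.coupled_promoters.to_csv(truth_dir / "coupled_promoters.tsv", sep="\t",
                               header=["sign"])
    pd.Series(sorted(t.discordant_genes)).to_csv(
        truth_dir / "discordant_genes.tsv", sep="\t", index=False,
        header=["gene_id"])
    paths["ground_truth"] = str(truth_dir)
    return paths
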