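"""Gene-metabolite association database: cross-layer Pearson edges with FDR,
the transcript/translation consistency filter, and methylation couplings.

Edges are Pearson correlations of per-stage replicate means (11 points by
default) on the raw abundance scale, with two-sided p from the t transform
(n - 2 df), BH across all tested pairs of a layer, and retention gates
|r| > r_threshold and q < q_threshold. A gene whose transcript-level and
protein-level correlations with the same metabolite disagree in sign is
"debatable" and the gene-metabolite pair is dropped from the database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["source", "target", "layer", "r", "p_value", "q_value", "sign"]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment r and two-sided p (t transform, n - 2 df).

    Returns (nan, nan) for zero-variance input (such pairs are excluded
    upstream rather than scored).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must have equal length")
    if x.size < 3:
        raise InputError("need at least 3 points for a correlation p-value")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r and p between rows of ``a`` and rows of ``b``.

    Both frames are features x stages with identical stage columns. Rows with
    zero variance yield NaN (excluded from any downstream family).
    """
    if list(a.columns) != list(b.columns):
        raise InputError("stage columns of the two matrices differ")
    n = a.shape[1]
    xa = a.to_numpy(dtype=float)
    xb = b.to_numpy(dtype=float)
    za = _standardize_rows(xa)
    zb = _standardize_rows(xb)
    r = za @ zb.T / (n - 1)
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return (pd.DataFrame(r, index=a.index, columns=b.index),
            pd.DataFrame(p, index=a.index, columns=b.index))


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[(sd == 0).ravel()] = np.nan
    return z


def build_association_edges(
    feature_means: pd.DataFrame,
    metabolite_means: pd.DataFrame,
    layer: str,
    feature_ids=None,
    metabolite_ids=None,
    r_threshold: float = 0.85,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Significant feature-metabolite correlation edges for one layer.

    ``feature_means`` / ``metabolite_means`` are features x stages stage-mean
    matrices on the raw scale; ``feature_ids`` / ``metabolite_ids`` restrict
    the tested pairs (typically DEGs/DEPs vs DAMs). BH runs across all tested
    pairs of the layer; retained edges satisfy |r| > r_threshold and
    q < q_threshold.
    """
    f = feature_means if feature_ids is None else \
        feature_means.loc[feature_means.index.intersection(pd.Index(feature_ids))]
    m = metabolite_means if metabolite_ids is None else \
        metabolite_means.loc[metabolite_means.index.intersection(pd.Index(metabolite_ids))]
    if f.empty or m.empty:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    r, p = correlation_matrix(f, m)
    r_flat = r.to_numpy().ravel()
    p_flat = p.to_numpy().ravel()
    finite = np.isfinite(p_flat)
    q_flat = np.full_like(p_flat, np.nan)
    if finite.any():
        q_flat[finite] = _bh(p_flat[finite])
    keep = finite & (np.abs(r_flat) > r_threshold) & (q_flat < q_threshold)
    if not keep.any():
        return pd.DataFrame(columns=EDGE_COLUMNS)
    src_idx, tgt_idx = np.divmod(keep.nonzero()[0], len(m.index))
    return pd.DataFrame({
        "source": f.index.to_numpy()[src_idx],
        "target": m.index.to_numpy()[tgt_idx],
        "layer": layer,
        "r": r_flat[keep],
        "p_value": p_flat[keep],
        "q_value": q_flat[keep],
        "sign": np.where(r_flat[keep] >= 0, "+", "-"),
    })


def _bh(p: np.ndarray) -> np.ndarray:
    from .differential import bh_adjust

    return bh_adjust(p)


@dataclass
class GeneMetaboliteDatabase:
    """Post-filter association database.

    ``edges`` holds the retained transcript-metabolite and protein-metabolite
    edges; ``removed_pairs`` records the (gene, metabolite) pairs dropped by
    the consistency filter. Optional cluster assignments and metabolite
    classes travel with the edges for grouping/reporting.
    """

    edges: pd.DataFrame
    removed_pairs: pd.DataFrame
    metabolite_clusters: pd.DataFrame | None = None
    class_of: pd.Series | None = None

    def gene_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["layer"] == "transcript-metabolite"]

    def genes_for_metabolites(self, metabolite_ids) -> set[str]:
        ge = self.gene_edges()
        return set(ge.loc[ge["target"].isin(set(metabolite_ids)), "source"])

    def drop_metabolite(self, metabolite_id: str) -> "GeneMetaboliteDatabase":
        return GeneMetaboliteDatabase(
            edges=self.edges[self.edges["target"] != metabolite_id].copy(),
            removed_pairs=self.removed_pairs,
            metabolite_clusters=self.metabolite_clusters,
            class_of=self.class_of,
        )


def consistency_filter(
    transcript_edges: pd.DataFrame,
    protein_edges: pd.DataFrame,
    protein_to_gene: pd.Series,
    metabolite_clusters: pd.DataFrame | None = None,
    class_of: pd.Series | None = None,
) -> GeneMetaboliteDatabase:
    """Remove gene-metabolite pairs with discordant transcript/protein signs.

    For every (gene, metabolite) with both a transcript edge and a protein
    edge: if the two signs differ, the pair (both edges) is removed. Genes
    without a detected protein, and concordant pairs, pass through.
    """
    unknown = set(protein_edges["source"]) - set(protein_to_gene.index)
    if unknown:
        raise InputError(f"protein(s) not mapped to a gene: {sorted(unknown)[:5]}")
    prot = protein_edges.copy()
    prot["gene"] = protein_to_gene.reindex(prot["source"]).to_numpy()
    tr_sign = transcript_edges.set_index(["source", "target"])["sign"]
    removed = []
    for row in prot.itertuples(index=False):
        key = (row.gene, row.target)
        if key in tr_sign.index and tr_sign.loc[key] != row.sign:
            removed.append({"gene": row.gene, "metabolite": row.target,
                            "transcript_sign": tr_sign.loc[key],
                            "protein_sign": row.sign})
    removed = pd.DataFrame(removed,
                           columns=["gene", "metabolite", "transcript_sign",
                                    "protein_sign"])
    bad = set(zip(removed["gene"], removed["metabolite"]))
    tr_mask = np.array([(s, t) not in bad
                        for s, t in zip(transcript_edges["source"],
                                        transcript_edges["target"])], dtype=bool)
    pr_mask = np.array([(g, t) not in bad
                        for g, t in zip(prot["gene"], prot["target"])],
                       dtype=bool)
    tr_keep = transcript_edges.loc[tr_mask]
    pr_keep = prot.loc[pr_mask].drop(columns="gene")
    frames = [df for df in (tr_keep, pr_keep) if len(df)]
    edges = pd.concat(frames, ignore_index=True) if frames else \
        tr_keep.reset_index(drop=True)
    return GeneMetaboliteDatabase(edges=edges, removed_pairs=removed,
                                  metabolite_clusters=metabolite_clusters,
                                  class_of=class_of)


def methylation_expression_edges(
    promoter_levels: pd.DataFrame,
    expression_means: pd.DataFrame,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene correlation of promoter methylation with expression.

    ``promoter_levels`` and ``expression_means`` are genes x stages; genes
    with an undefined promoter level in any stage, or zero variance on either
    side, are skipped (logged). Both signs are reported; the only gate is the
    BH q across tested genes.
    """
    common = promoter_levels.index.intersection(expression_means.index)
    pl = promoter_levels.loc[common].to_numpy(dtype=float)
    ex = expression_means.loc[common].to_numpy(dtype=float)
    ok = (np.isfinite(pl).all(axis=1)
          & (pl.std(axis=1) > 0) & (ex.std(axis=1) > 0))
    n_skip = int((~ok).sum())
    if n_skip:
        log.info("methylation-expression: skipped %d genes with undefined or "
                 "constant promoter levels", n_skip)
    pl, ex = pl[ok], ex[ok]
    genes = common[ok]
    if len(genes) == 0:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    n = pl.shape[1]
    za = _standardize_rows(pl)
    zb = _standardize_rows(ex)
    r = np.clip((za * zb).sum(axis=1) / (n - 1), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) == 1.0] = 0.0
    q = _bh(p)
    keep = q < q_threshold
    return pd.DataFrame({
        "source": "promoter:" + genes[keep].astype(str),
        "target": genes[keep],
        "layer": "methylation-expression",
        "r": r[keep],
        "p_value": p[keep],
        "q_value": q[keep],
        "sign": np.where(r[keep] >= 0, "+", "-"),
    })


def genome_methylation_dam_correlation(
    global_levels: pd.Series,
    dam_means: pd.DataFrame,
    clusters: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation of each DAM with the single genome-wide methylation series.

    Returns (per-metabolite edges, per-cluster summary with median r). The
    edge list is unfiltered (all finite correlations with p/q) since the
    interest is the sign pattern per trend cluster.
    """
    g = global_levels.reindex(dam_means.columns).to_numpy(dtype=float)
    if np.isnan(g).any():
        raise InputError("global methylation series misses a stage")
    rows = []
    for mid, series in dam_means.iterrows():
        r, p = pearson_r(g, series.to_numpy())
        if np.isnan(r):
            continue
        rows.append({"source": "genome:C", "target": mid,
                     "layer": "genome-methylation-metabolite",
                     "r": r, "p_value": p})
    edges = pd.DataFrame(rows, columns=["source", "target", "layer", "r",
                                        "p_value"])
    if len(edges):
        edges["q_value"] = _bh(edges["p_value"].to_numpy())
        edges["sign"] = np.where(edges["r"] >= 0, "+", "-")
    else:
        edges["q_value"] = []
        edges["sign"] = []
    if clusters is None or edges.empty:
        return edges, pd.DataFrame(columns=["cluster_label", "median_r", "n"])
    lab = clusters.set_index("feature_id")["cluster_label"]
    edges_lab = edges.assign(cluster=lab.reindex(edges["target"]).to_numpy())
    summary = (edges_lab.dropna(subset=["cluster"])
               .groupby("cluster")["r"]
               .agg(median_r="median", n="size")
               .reset_index()
               .rename(columns={"cluster": "cluster_label"}))
    return edges, summary
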