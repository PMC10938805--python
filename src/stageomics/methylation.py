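"""Region methylation levels, metagene profiles, DMR calling and siRNA RPM.

Levels are always weighted (pooled-count) levels: sum(meth) / sum(meth +
unmeth) over the covered sites of a context inside a region — an interval
with no covered site has an *undefined* level (NaN), never zero.

DMRs are called per context with a sliding window over replicate-pooled
counts: Fisher's exact test on the 2x2 (meth/unmeth x stage) table, BH across
all tested windows of the context, a minimum-site gate, an absolute level
difference gate, and merging of overlapping/adjacent significant windows of
the same sign.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import assign_points_to_intervals, overlap_interval_pairs
from .errors import InputError
from .io import CONTEXTS, GeneModel, Methylome, promoter_table

log = logging.getLogger(__name__)

DMR_COLUMNS = ["chrom", "start", "end", "context", "stage_a", "stage_b",
               "level_a", "level_b", "delta", "p_value", "q_value", "n_sites"]


# ---------------------------------------------------------------------------
# region levels


def region_methylation_level(
    methylome: Methylome,
    chrom: str,
    start: int,
    end: int,
    context: str | None = None,
    stage: str | None = None,
) -> float:
    """Pooled methylation level of [start, end) — NaN when no covered site.

    ``context=None`` pools all three contexts ("C methylation");
    ``stage=None`` pools all samples, otherwise the stage's replicates.
    """
    sites = methylome.sites
    mask = ((sites["chrom"] == chrom).to_numpy()
            & (sites["pos"].to_numpy() >= start)
            & (sites["pos"].to_numpy() < end)
            & methylome.context_mask(context))
    cols = methylome.sample_columns(stage)
    meth = methylome.meth[np.ix_(mask.nonzero()[0], cols)].sum()
    total = methylome.total[np.ix_(mask.nonzero()[0], cols)].sum()
    return float(meth) / float(total) if total > 0 else float("nan")


def stage_level_series(
    methylome: Methylome, context: str | None = None,
    chrom: str | None = None, start: int | None = None, end: int | None = None,
) -> pd.Series:
    """Per-stage pooled level of a region (default: the whole methylome)."""
    mask = methylome.context_mask(context)
    if chrom is not None:
        mask &= (methylome.sites["chrom"] == chrom).to_numpy()
        pos = methylome.sites["pos"].to_numpy()
        if start is not None:
            mask &= pos >= start
        if end is not None:
            mask &= pos < end
    idx = mask.nonzero()[0]
    out = {}
    for stage in methylome.design.stages:
        cols = methylome.sample_columns(stage)
        total = methylome.total[np.ix_(idx, cols)].sum()
        meth = methylome.meth[np.ix_(idx, cols)].sum()
        out[stage] = meth / total if total > 0 else np.nan
    return pd.Series(out, name=f"level[{context or 'C'}]")


def promoter_level_matrix(
    methylome: Methylome,
    genes: list[GeneModel],
    upstream_bp: int = 2000,
    context: str | None = None,
) -> pd.DataFrame:
    """Per-gene, per-stage pooled promoter methylation level (genes x stages).

    All contexts are pooled by default (the "average cytosine methylation of
    the promoter"); genes whose promoter has no covered site in a stage get
    NaN for that stage.
    """
    proms = promoter_table(genes, upstream_bp)
    sites = methylome.sites
    ctx = methylome.context_mask(context)
    design = methylome.design
    n_stages = design.n_stages
    meth_stage = np.column_stack([methylome.meth[:, methylome.sample_columns(s)].sum(axis=1)
                                  for s in design.stages])
    total_stage = np.column_stack([methylome.total[:, methylome.sample_columns(s)].sum(axis=1)
                                   for s in design.stages])
    m_sum = np.zeros((len(proms), n_stages))
    t_sum = np.zeros((len(proms), n_stages))
    for chrom, chrom_proms in proms.groupby("chrom", sort=False):
        on_chrom = ((sites["chrom"] == chrom).to_numpy() & ctx).nonzero()[0]
        if on_chrom.size == 0:
            continue
        p_idx, g_idx = assign_points_to_intervals(
            sites["pos"].to_numpy()[on_chrom],
            chrom_proms["start"].to_numpy(),
            chrom_proms["end"].to_numpy(),
        )
        rows = proms.index.get_indexer(chrom_proms.index[g_idx])
        np.add.at(m_sum, rows, meth_stage[on_chrom[p_idx]])
        np.add.at(t_sum, rows, total_stage[on_chrom[p_idx]])
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(t_sum > 0, m_sum / np.where(t_sum > 0, t_sum, 1), np.nan)
    return pd.DataFrame(levels, index=proms.index, columns=list(design.stages))


# ---------------------------------------------------------------------------
# metagene profile


def metagene_profile(
    methylome: Methylome,
    genes: list[GeneModel],
    n_body_bins: int = 40,
    flank_bp: int = 2000,
    flank_bin_bp: int = 100,
    contexts=CONTEXTS,
    stages=None,
) -> pd.DataFrame:
    """Average methylation over genes rescaled to fixed bins, per context/stage.

    Bins: ``flank_bp / flank_bin_bp`` upstream bins, ``n_body_bins`` body bins
    (gene rescaled), then downstream bins; minus-strand genes are mirrored so
    bin 0 is always the far 5' end. Bin level = pooled count level across all
    genes' sites falling in the bin (NaN when uncovered). Columns: context,
    stage, bin_index, segment, level.
    """
    if not genes:
        raise InputError("need at least one gene for a metagene profile")
    n_flank_bins = flank_bp // flank_bin_bp
    n_bins = 2 * n_flank_bins + n_body_bins
    design = methylome.design
    stages = list(stages) if stages is not None else list(design.stages)

    sites = methylome.sites
    pos_all = sites["pos"].to_numpy()
    bin_ids = []
    site_rows = []
    for chrom in pd.unique(pd.Series([g.chrom for g in genes])):
        chrom_genes = [g for g in genes if g.chrom == chrom]
        on_chrom = (sites["chrom"] == chrom).to_numpy().nonzero()[0]
        if on_chrom.size == 0:
            continue
        starts = np.array([g.start - flank_bp for g in chrom_genes])
        ends = np.array([g.end + flank_bp for g in chrom_genes])
        p_idx, g_idx = assign_points_to_intervals(pos_all[on_chrom], starts, ends)
        if p_idx.size == 0:
            continue
        pos = pos_all[on_chrom[p_idx]]
        g_start = np.array([chrom_genes[i].start for i in g_idx])
        g_end = np.array([chrom_genes[i].end for i in g_idx])
        minus = np.array([chrom_genes[i].strand == "-" for i in g_idx])
        g_len = g_end - g_start

        bin_idx = np.empty(pos.size, dtype=np.int64)
        before = pos < g_start
        after = pos >= g_end
        body = ~before & ~after
        bin_idx[before] = (pos[before] - (g_start[before] - flank_bp)) // flank_bin_bp
        bin_idx[body] = n_flank_bins + (
            (pos[body] - g_start[body]) * n_body_bins // g_len[body])
        bin_idx[after] = n_flank_bins + n_body_bins + (
            (pos[after] - g_end[after]) // flank_bin_bp)
        # mirror minus-strand genes: upstream must be the 5' flank
        bin_idx[minus] = n_bins - 1 - bin_idx[minus]
        bin_ids.append(bin_idx)
        site_rows.append(on_chrom[p_idx])
    if not bin_ids:
        return pd.DataFrame(columns=["context", "stage", "bin_index", "segment",
                                     "level"])
    bin_idx = np.concatenate(bin_ids)
    site_rows = np.concatenate(site_rows)

    segment = np.array(["upstream"] * n_flank_bins + ["body"] * n_body_bins
                       + ["downstream"] * n_flank_bins)
    records = []
    ctx_codes = sites["context"].to_numpy()
    for context in contexts:
        in_ctx = ctx_codes[site_rows] == context
        rows_c = site_rows[in_ctx]
        bins_c = bin_idx[in_ctx]
        for stage in stages:
            cols = methylome.sample_columns(stage)
            meth = methylome.meth[np.ix_(rows_c, cols)].sum(axis=1) if rows_c.size else np.empty(0)
            total = methylome.total[np.ix_(rows_c, cols)].sum(axis=1) if rows_c.size else np.empty(0)
            m_bin = np.bincount(bins_c, weights=meth, minlength=n_bins)
            t_bin = np.bincount(bins_c, weights=total, minlength=n_bins)
            with np.errstate(invalid="ignore", divide="ignore"):
                level = np.where(t_bin > 0, m_bin / np.where(t_bin > 0, t_bin, 1),
                                 np.nan)
            for b in range(n_bins):
                records.append((context, stage, b, segment[b], level[b]))
    return pd.DataFrame(records, columns=["context", "stage", "bin_index",
                                          "segment", "level"])


# ---------------------------------------------------------------------------
# DMR calling


def _fisher_pvalues(tables: np.ndarray) -> np.ndarray:
    """Two-sided Fisher exact p for an array of 2x2 tables (n, 4):
    [meth_a, unmeth_a, meth_b, unmeth_b]."""
    out = np.empty(len(tables))
    cache: dict[tuple[int, int, int, int], float] = {}
    for i, (ma, ua, mb, ub) in enumerate(tables):
        key = (int(ma), int(ua), int(mb), int(ub))
        p = cache.get(key)
        if p is None:
            p = stats.fisher_exact([[key[0], key[1]], [key[2], key[3]]])[1]
            cache[key] = p
        out[i] = p
    return out


def call_dmrs(
    methylome: Methylome,
    stage_a: str,
    stage_b: str,
    contexts=CONTEXTS,
    window_bp: int = 100,
    step_bp: int = 50,
    min_sites: int = 4,
    delta_min: float = 0.1,
    q_threshold: float = 0.05,
    min_windows: int = 2,
) -> pd.DataFrame:
    """Differentially methylated regions between two stages (see module doc).

    Replicates are pooled within each stage. Windows with fewer than
    ``min_sites`` sites are skipped (counted in the log). Overlapping or
    adjacent (gap <= step_bp) significant windows of the same context and
    delta sign are merged; merged levels are recomputed from the pooled
    counts of all sites in the merged interval.

    ``min_windows`` is a consistency rule: a reported DMR must be supported
    by at least that many significant windows. At typical WGBS depth a single
    window holding only ``min_sites`` sites is dominated by sampling noise,
    and because windows overlap, one fluctuation gets several chances to pass
    the gates; demanding two consecutive significant windows suppresses those
    single-window artefacts while leaving any real region (which spans
    several windows) untouched. Set ``min_windows=1`` for plain single-window
    reporting.
    """
    if window_bp % step_bp != 0:
        raise InputError("window_bp must be a multiple of step_bp")
    meth_a, total_a = methylome.stage_counts(stage_a)
    meth_b, total_b = methylome.stage_counts(stage_b)
    sites = methylome.sites
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    k = window_bp // step_bp

    all_dmrs = []
    n_skipped = 0
    for context in contexts:
        ctx_mask = methylome.context_mask(context)
        for chrom in pd.unique(chroms):
            mask = ctx_mask & (chroms == chrom)
            idx = mask.nonzero()[0]
            if idx.size == 0:
                continue
            p = pos[idx]
            # windows start at multiples of step_bp; site in window w iff
            # w*step <= pos < w*step + window
            base_w = p // step_bp
            w_ids = np.concatenate([base_w - j for j in range(k)])
            s_ids = np.tile(idx, k)
            keep = w_ids >= 0
            w_ids, s_ids = w_ids[keep], s_ids[keep]
            df = pd.DataFrame({
                "w": w_ids,
                "ma": meth_a[s_ids], "ta": total_a[s_ids],
                "mb": meth_b[s_ids], "tb": total_b[s_ids],
            })
            agg = df.groupby("w").agg(
                n_sites=("ma", "size"), ma=("ma", "sum"), ta=("ta", "sum"),
                mb=("mb", "sum"), tb=("tb", "sum"))
            tested = agg[(agg["n_sites"] >= min_sites)
                         & (agg["ta"] > 0) & (agg["tb"] > 0)]
            n_skipped += len(agg) - len(tested)
            if tested.empty:
                continue
            tables = np.column_stack([
                tested["ma"], tested["ta"] - tested["ma"],
                tested["mb"], tested["tb"] - tested["mb"],
            ]).astype(np.int64)
            pvals = _fisher_pvalues(tables)
            level_a = tested["ma"] / tested["ta"]
            level_b = tested["mb"] / tested["tb"]
            qvals = _bh(pvals)
            delta = (level_b - level_a).to_numpy()
            sig = (qvals < q_threshold) & (np.abs(delta) >= delta_min)
            if not sig.any():
                continue
            win = pd.DataFrame({
                "start": tested.index.to_numpy()[sig] * step_bp,
                "level_a": level_a.to_numpy()[sig],
                "level_b": level_b.to_numpy()[sig],
                "delta": delta[sig],
                "p_value": pvals[sig],
                "q_value": qvals[sig],
                "n_sites": tested["n_sites"].to_numpy()[sig],
            }).sort_values("start")
            win["end"] = win["start"] + window_bp
            merged = _merge_windows(win, step_bp)
            merged = merged[merged["n_windows"] >= min_windows]
            if merged.empty:
                continue
            merged = _refine_merged(merged, p, idx, meth_a, total_a,
                                    meth_b, total_b)
            # the delta gate must hold on the merged, recomputed estimate too
            merged = merged[merged["delta"].abs() >= delta_min]
            if merged.empty:
                continue
            merged.insert(0, "chrom", chrom)
            merged.insert(3, "context", context)
            merged.insert(4, "stage_a", stage_a)
            merged.insert(5, "stage_b", stage_b)
            all_dmrs.append(merged)
    if n_skipped:
        log.info("DMR %s vs %s: skipped %d windows below min_sites/coverage",
                 stage_a, stage_b, n_skipped)
    if not all_dmrs:
        return pd.DataFrame(columns=DMR_COLUMNS)
    out = pd.concat(all_dmrs, ignore_index=True)
    return out[DMR_COLUMNS].sort_values(
        ["chrom", "start", "context"]).reset_index(drop=True)


def _bh(p: np.ndarray) -> np.ndarray:
    from .differential import bh_adjust

    return bh_adjust(p)


def _merge_windows(win: pd.DataFrame, step_bp: int) -> pd.DataFrame:
    """Merge overlapping/adjacent (gap <= step) windows of the same sign."""
    rows = []
    cur = None
    for rec in win.itertuples(index=False):
        sign = np.sign(rec.delta)
        if cur is not None and rec.start - cur["end"] <= step_bp \
                and sign == cur["sign"]:
            cur["end"] = max(cur["end"], rec.end)
            cur["p_value"] = min(cur["p_value"], rec.p_value)
            cur["q_value"] = min(cur["q_value"], rec.q_value)
            cur["n_windows"] += 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"start": rec.start, "end": rec.end, "sign": sign,
                   "p_value": rec.p_value, "q_value": rec.q_value,
                   "n_windows": 1}
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(rows)


def _refine_merged(merged: pd.DataFrame, p: np.ndarray, idx: np.ndarray,
                   meth_a, total_a, meth_b, total_b) -> pd.DataFrame:
    """Recompute pooled levels/site counts over each merged interval."""
    level_a, level_b, n_sites = [], [], []
    for rec in merged.itertuples(index=False):
        inside = (p >= rec.start) & (p < rec.end)
        rows = idx[inside]
        ta, tb = total_a[rows].sum(), total_b[rows].sum()
        level_a.append(meth_a[rows].sum() / ta if ta else np.nan)
        level_b.append(meth_b[rows].sum() / tb if tb else np.nan)
        n_sites.append(int(inside.sum()))
    out = merged.drop(columns=["sign", "n_windows"]).copy()
    out["level_a"] = level_a
    out["level_b"] = level_b
    out["delta"] = out["level_b"] - out["level_a"]
    out["n_sites"] = n_sites
    return out


# ---------------------------------------------------------------------------
# promoter overlap and siRNA abundance


def promoter_dmr_genes(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    upstream_bp: int = 2000,
) -> tuple[dict[str, list[int]], pd.DataFrame]:
    """Genes whose promoter shares >= 1 base with a DMR.

    Returns (gene -> list of DMR row indices, per-gene context flags): the
    flags frame has one boolean column per context plus ``any``.
    """
    proms = promoter_table(genes, upstream_bp)
    gene_ids = list(proms.index)
    mapping: dict[str, list[int]] = {}
    flags = pd.DataFrame(False, index=proms.index, columns=list(CONTEXTS))
    if len(dmrs):
        for chrom, chrom_proms in proms.groupby("chrom", sort=False):
            d = dmrs[dmrs["chrom"] == chrom]
            if d.empty:
                continue
            a_idx, b_idx = overlap_interval_pairs(
                chrom_proms["start"].to_numpy(), chrom_proms["end"].to_numpy(),
                d["start"].to_numpy(), d["end"].to_numpy(),
            )
            for ai, bi in zip(a_idx, b_idx):
                gid = chrom_proms.index[ai]
                row = d.index[bi]
                mapping.setdefault(gid, []).append(int(row))
                flags.loc[gid, dmrs.loc[row, "context"]] = True
    flags["any"] = flags[list(CONTEXTS)].any(axis=1)
    return mapping, flags


def sirna_rpm_in_regions(
    clusters: pd.DataFrame,
    regions: pd.DataFrame,
    total_clean_reads: dict,
) -> pd.DataFrame:
    """Reads-per-million of 24-nt siRNA clusters per region and sample.

    A cluster is assigned to a region iff its midpoint lies inside the region
    (counted once, fully). RPM = 1e6 * sum(reads) / total_clean_reads.
    """
    sample_cols = [c for c in clusters.columns
                   if c not in ("chrom", "start", "end", "name")]
    for sid, total in total_clean_reads.items():
        if total <= 0:
            raise InputError(f"total_clean_reads for {sid} must be positive")
    regions = regions.reset_index(drop=True)
    rpm = pd.DataFrame(0.0, index=regions.index, columns=sample_cols)
    mid = ((clusters["start"] + clusters["end"]) // 2).to_numpy()
    for chrom, reg in regions.groupby("chrom", sort=False):
        on_chrom = (clusters["chrom"] == chrom).to_numpy().nonzero()[0]
        if on_chrom.size == 0:
            continue
        c_idx, r_idx = assign_points_to_intervals(
            mid[on_chrom], reg["start"].to_numpy(), reg["end"].to_numpy())
        for ci, ri in zip(on_chrom[c_idx], reg.index[r_idx]):
            rpm.loc[ri, sample_cols] += clusters.loc[clusters.index[ci],
                                                     sample_cols].to_numpy()
    totals = _totals_by_column(sample_cols, total_clean_reads)
    return rpm * 1e6 / totals


def _totals_by_column(sample_cols, total_clean_reads: dict) -> pd.Series:
    out = {}
    for col in sample_cols:
        if col in total_clean_reads:
            out[col] = total_clean_reads[col]
        else:
            stage, _, rep = col.rpartition("_R")
            key = (stage, int(rep))
            if key not in total_clean_reads:
                raise InputError(f"no total_clean_reads for sample {col!r}")
            out[col] = total_clean_reads[key]
    return pd.Series(out)
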