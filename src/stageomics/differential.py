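"""Stage-pairwise differential calling with Benjamini-Hochberg FDR.

One engine serves all three layers (DAM / DEP / DEG): a Welch two-sample t
test on log2(value + pseudocount) across replicates, with significance
requiring both |log2 fold-change| >= log2(fc_threshold) on the raw stage
means and BH q below the FDR threshold. The FDR family is all features of
one layer within one stage pair.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io import FeatureTable

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["feature_id", "layer", "stage_a", "stage_b", "log2fc",
                  "p_value", "q_value", "direction", "significant"]


def bh_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values, capped at 1,
    returned in the input order. ``method='by'`` applies the
    Benjamini-Yekutieli correction factor for arbitrary dependence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    if method == "by":
        ranked *= np.sum(1.0 / np.arange(1, m + 1))
    elif method != "bh":
        raise InputError(f"unknown FDR method {method!r}")
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _welch(x_a: np.ndarray, x_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t test along axis 1; returns (t, two-sided p)."""
    n_a, n_b = x_a.shape[1], x_b.shape[1]
    m_a, m_b = x_a.mean(axis=1), x_b.mean(axis=1)
    v_a = x_a.var(axis=1, ddof=1)
    v_b = x_b.var(axis=1, ddof=1)
    se2 = v_a / n_a + v_b / n_b
    diff = m_b - m_a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (v_a**2 / (n_a**2 * (n_a - 1)) + v_b**2 / (n_b**2 * (n_b - 1)))
    # degenerate: both groups constant
    zero = se2 == 0
    t[zero] = np.where(diff[zero] == 0, 0.0, np.inf * np.sign(diff[zero]))
    df = np.where(np.isfinite(df), df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[zero & (diff == 0)] = 1.0
    p[zero & (diff != 0)] = 0.0
    return t, np.clip(p, 0.0, 1.0)


def call_differential(
    table: FeatureTable,
    stage_a: str,
    stage_b: str,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    pseudocount: float = 1.0,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Differential features between two stages of one layer.

    Returns one record per feature (columns ``RECORD_COLUMNS``); features
    with all-zero values in both stages are excluded and logged.
    """
    design = table.design
    ia, ib = design.stage_index(stage_a), design.stage_index(stage_b)
    if ia == ib:
        raise InputError("stage_a and stage_b must differ")
    if design.n_replicates < 2:
        raise InputError("need >= 2 replicates per stage for a t test")
    raw_a = table.stage_values(stage_a).to_numpy(dtype=float)
    raw_b = table.stage_values(stage_b).to_numpy(dtype=float)

    keep = ~((raw_a == 0).all(axis=1) & (raw_b == 0).all(axis=1))
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("%s %s vs %s: excluded %d all-zero features",
                 table.layer, stage_a, stage_b, n_dropped)
    raw_a, raw_b = raw_a[keep], raw_b[keep]
    ids = table.feature_ids[keep]

    log2fc = np.log2(raw_b.mean(axis=1) + pseudocount) \
        - np.log2(raw_a.mean(axis=1) + pseudocount)
    _t, p = _welch(np.log2(raw_a + pseudocount), np.log2(raw_b + pseudocount))
    q = bh_adjust(p, method=fdr_method) if len(p) else p
    significant = (np.abs(log2fc) >= np.log2(fc_threshold)) & (q < q_threshold)
    return pd.DataFrame({
        "feature_id": ids,
        "layer": table.layer,
        "stage_a": stage_a,
        "stage_b": stage_b,
        "log2fc": log2fc,
        "p_value": p,
        "q_value": q,
        "direction": np.where(log2fc >= 0, "up", "down"),
        "significant": significant,
    })


def differential_all_pairs(
    table: FeatureTable,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    pseudocount: float = 1.0,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Run :func:`call_differential` over all C(n_stages, 2) stage pairs.

    A feature is a DAM/DEP/DEG iff it is significant in at least one pair.
    """
    frames = [
        call_differential(table, a, b, fc_threshold=fc_threshold,
                          q_threshold=q_threshold, pseudocount=pseudocount,
                          fdr_method=fdr_method)
        for a, b in table.design.all_pairs()
    ]
    return pd.concat(frames, ignore_index=True)


def differential_features(records: pd.DataFrame) -> set[str]:
    """Features significant in at least one stage pair."""
    return set(records.loc[records["significant"], "feature_id"])


def significant_for_pair(records: pd.DataFrame, stage_a: str,
                         stage_b: str) -> pd.DataFrame:
    mask = (records["stage_a"] == stage_a) & (records["stage_b"] == stage_b)
    return records[mask & records["significant"]]
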