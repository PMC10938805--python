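"""Trend clustering of differential metabolites into eight shape classes.

Stage-mean series are z-standardised and clustered with k-means (k = 8,
Euclidean, multiple restarts, fixed seed); each centroid is then anchored to
the nearest archetypal shape (labels I-VIII) by correlation distance through
an optimal one-to-one assignment, so labels are a bijection and carry the
same meaning on any dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering, KMeans

from .errors import InputError
from .simulate import ARCHETYPE_LABELS, make_archetypes


def zscore_series(series) -> tuple[np.ndarray, bool]:
    """(x - mean) / sd with sample sd (ddof=1).

    A constant series has no shape: it maps to the all-zero vector and is
    flagged degenerate (second return value).
    """
    x = np.asarray(series, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def zscore_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scores plus a per-row degenerate flag."""
    arr = df.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    degenerate = (sd == 0) | ~np.isfinite(sd)
    safe = np.where(degenerate, 1.0, sd)
    z = (arr - arr.mean(axis=1, keepdims=True)) / safe[:, None]
    z[degenerate] = 0.0
    return (pd.DataFrame(z, index=df.index, columns=df.columns),
            pd.Series(degenerate, index=df.index, name="degenerate"))


def _label_map(centroids: np.ndarray, archetypes: pd.DataFrame) -> dict[int, str]:
    """Bijective cluster -> archetype-label map via correlation distance.

    Cost = 1 - Pearson r between centroid and archetype; solved as an optimal
    assignment, with deterministic tie-breaking by label order.
    """
    arch = archetypes.to_numpy()
    cost = np.empty((len(centroids), len(arch)))
    for i, c in enumerate(centroids):
        csd = c.std()
        for j, a in enumerate(arch):
            if csd == 0 or a.std() == 0:
                cost[i, j] = 1.0
            else:
                cost[i, j] = 1.0 - np.corrcoef(c, a)[0, 1]
    # tiny label-order penalty makes ties resolve toward earlier labels
    cost += np.arange(len(arch))[None, :] * 1e-12
    rows, cols = linear_sum_assignment(cost)
    labels = list(archetypes.index)
    return {int(r): labels[c] for r, c in zip(rows, cols)}


def cluster_trends(
    z_matrix: pd.DataFrame,
    k: int = 8,
    seed: int = 0,
    n_init: int = 20,
    method: str = "kmeans",
    archetypes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cluster z-scored stage series and label clusters I..VIII.

    Rows are features, columns the ordered stages. Returns a DataFrame with
    feature_id, cluster_label and centroid_distance (Euclidean distance to
    the assigned centroid). Rows are processed in a canonical (sorted-id)
    order so the result is invariant to input row order.
    """
    if len(z_matrix) < k:
        raise InputError(f"need at least k={k} rows to cluster, got {len(z_matrix)}")
    if archetypes is None:
        archetypes = make_archetypes(z_matrix.shape[1])
    if k != len(archetypes):
        raise InputError("k must match the number of archetype labels")

    canonical = z_matrix.sort_index()
    X = canonical.to_numpy(dtype=float)
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        assign = km.fit_predict(X)
        centroids = km.cluster_centers_
    elif method == "ward":
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        assign = model.fit_predict(X)
        centroids = np.vstack([X[assign == c].mean(axis=0) for c in range(k)])
    else:
        raise InputError(f"unknown clustering method {method!r}")

    label_of = _label_map(centroids, archetypes)
    dist = np.linalg.norm(X - centroids[assign], axis=1)
    out = pd.DataFrame({
        "feature_id": canonical.index,
        "cluster_label": [label_of[int(c)] for c in assign],
        "centroid_distance": dist,
    })
    out = out.set_index("feature_id").reindex(z_matrix.index).reset_index()
    out = out.rename(columns={out.columns[0]: "feature_id"})
    return out


def cluster_dam_trends(
    stage_means: pd.DataFrame,
    dam_ids,
    seed: int = 0,
    log_transform: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """Convenience wrapper: z-score (optionally log2) DAM stage means and
    cluster them. ``stage_means`` is features x stages on the raw scale."""
    dam_ids = [f for f in dam_ids if f in stage_means.index]
    sub = stage_means.loc[sorted(dam_ids)]
    if log_transform:
        sub = np.log2(sub + 1.0)
    z, _deg = zscore_matrix(sub)
    return cluster_trends(z, seed=seed, **kwargs)
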