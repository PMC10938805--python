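"""Adjacent-stage transition accounting.

For each of the n-1 adjacent stage pairs: the metabolites significantly
increased at the later stage, their class composition (the Table-1-style
class x transition matrix), the database genes correlated with them, the
intersection with that pair's DEGs ("correlated DEGs"), and the subset whose
promoter carries >= 1 DMR ("DMR-modified correlated DEGs").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import GeneMetaboliteDatabase
from .design import StageDesign

SUMMARY_COLUMNS = ["transition", "n_increased_metabolites", "n_correlated_genes",
                   "n_degs_pair", "n_correlated_degs", "n_dmr_modified",
                   "fraction_dmr_modified"]


def next_stage_increases(
    dam_records: pd.DataFrame, design: StageDesign,
) -> dict[tuple[str, str], set[str]]:
    """Metabolites significantly accumulated at the next stage, per adjacent
    pair (significant + direction up for exactly that pair)."""
    out: dict[tuple[str, str], set[str]] = {}
    for a, b in design.adjacent_pairs():
        mask = ((dam_records["stage_a"] == a) & (dam_records["stage_b"] == b)
                & dam_records["significant"] & (dam_records["direction"] == "up"))
        out[(a, b)] = set(dam_records.loc[mask, "feature_id"])
    return out


def class_transition_table(
    increase_sets: dict[tuple[str, str], set[str]],
    class_of: pd.Series | None,
    design: StageDesign,
) -> pd.DataFrame:
    """Class x transition count matrix (n_stages - 1 columns).

    Metabolites without a class are bucketed as "Others". Column sums equal
    the increase-set sizes.
    """
    cols = [f"{a} vs {b}" for a, b in design.adjacent_pairs()]
    counts: dict[str, dict[str, int]] = {}
    for (a, b), members in increase_sets.items():
        col = f"{a} vs {b}"
        for m in members:
            cls = "Others"
            if class_of is not None and m in class_of.index \
                    and pd.notna(class_of.loc[m]):
                cls = str(class_of.loc[m])
            counts.setdefault(cls, {}).setdefault(col, 0)
            counts[cls][col] += 1
    table = pd.DataFrame(counts).T.reindex(columns=cols).fillna(0).astype(int)
    table = table.sort_index()
    table.index.name = "metabolite_class"
    return table


def transition_correlated_degs(
    increase_sets: dict[tuple[str, str], set[str]],
    database: GeneMetaboliteDatabase,
    deg_records: pd.DataFrame,
    promoter_dmr_flags: pd.DataFrame,
    design: StageDesign,
) -> tuple[pd.DataFrame, dict[tuple[str, str], dict[str, set[str]]]]:
    """Per-transition funnel: correlated genes -> correlated DEGs ->
    DMR-modified correlated DEGs.

    * correlated genes: genes with a database edge to >= 1 metabolite of the
      transition's increased set;
    * correlated DEGs: correlated genes that are also significant DEGs for
      that same adjacent pair;
    * DMR-modified: correlated DEGs whose promoter overlaps >= 1 DMR.

    Returns (summary frame, per-transition sets).
    """
    dmr_genes = set(promoter_dmr_flags.index[promoter_dmr_flags["any"]]) \
        if "any" in promoter_dmr_flags.columns else set(promoter_dmr_flags.index)
    rows = []
    sets: dict[tuple[str, str], dict[str, set[str]]] = {}
    for a, b in design.adjacent_pairs():
        dams = increase_sets.get((a, b), set())
        correlated = database.genes_for_metabolites(dams)
        mask = ((deg_records["stage_a"] == a) & (deg_records["stage_b"] == b)
                & deg_records["significant"])
        degs = set(deg_records.loc[mask, "feature_id"])
        correlated_degs = correlated & degs
        dmr_modified = correlated_degs & dmr_genes
        frac = len(dmr_modified) / len(correlated_degs) if correlated_degs \
            else np.nan
        rows.append({
            "transition": f"{a} vs {b}",
            "n_increased_metabolites": len(dams),
            "n_correlated_genes": len(correlated),
            "n_degs_pair": len(degs),
            "n_correlated_degs": len(correlated_degs),
            "n_dmr_modified": len(dmr_modified),
            "fraction_dmr_modified": frac,
        })
        sets[(a, b)] = {"increased_metabolites": dams,
                        "correlated_genes": correlated,
                        "degs": degs,
                        "correlated_degs": correlated_degs,
                        "dmr_modified_correlated_degs": dmr_modified}
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS), sets
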