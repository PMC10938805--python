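"""Data model and on-disk formats for stage-series multi-omics data.

Conventions
-----------
* All genomic coordinates are 0-based, half-open internally. Cytosine
  reports are read as 1-based (the Bismark cytosine-report dialect) and
  converted on ingest; BED input/output stays 0-based.
* Stage tables are TSV: a ``feature_id`` column, one column per
  (stage, replicate) named ``<stage>_R<k>``, and an optional ``class``
  column for metabolites.
* Zero-coverage methylation sites are retained but excluded from level
  computation (missing, not zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StageDesign
from .errors import InputError

log = logging.getLogger(__name__)

LAYERS = ("metabolome", "proteome", "transcriptome")
CONTEXTS = ("CG", "CHG", "CHH")

# representative trinucleotides used when writing synthetic cytosine reports
_TRINUCLEOTIDE = {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# feature tables


@dataclass
class FeatureTable:
    """Abundance matrix of one omics layer: features x (stage, replicate).

    ``values`` is indexed by feature id with the design's flat sample columns
    in design order. ``class_of`` optionally maps metabolite ids to a
    metabolite-class label.
    """

    layer: str
    values: pd.DataFrame
    design: StageDesign = field(default_factory=StageDesign)
    class_of: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise InputError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        expected = self.design.columns()
        missing = set(expected) - set(self.values.columns)
        extra = set(self.values.columns) - set(expected)
        if missing or extra:
            raise InputError(
                f"{self.layer} table columns do not cover the design "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        self.values = self.values[expected]
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise InputError(f"duplicate feature_id {dup[0]!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise InputError(f"{self.layer} table contains non-finite values")
        if (arr < 0).any():
            raise InputError(f"{self.layer} table contains negative values")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    def stage_means(self) -> pd.DataFrame:
        """Per-stage replicate means: features x stages (design order)."""
        cols = {s: [f"{s}_R{k}" for k in range(1, self.design.n_replicates + 1)]
                for s in self.design.stages}
        out = pd.DataFrame(
            {s: self.values[c].mean(axis=1) for s, c in cols.items()},
            index=self.values.index,
        )
        return out[list(self.design.stages)]

    def stage_values(self, stage: str) -> pd.DataFrame:
        if stage not in self.design.stages:
            raise InputError(f"unknown stage {stage!r}")
        cols = [f"{stage}_R{k}" for k in range(1, self.design.n_replicates + 1)]
        return self.values[cols]


def read_stage_table(path, layer: str, design: StageDesign | None = None) -> FeatureTable:
    """Read a TSV stage table (feature_id + <stage>_R<k> columns [+ class])."""
    design = design or StageDesign()
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    if "feature_id" not in df.columns:
        raise InputError(f"{path}: missing feature_id column")
    dup = df["feature_id"][df["feature_id"].duplicated()]
    if len(dup):
        raise InputError(f"{path}: duplicate feature_id {dup.iloc[0]!r}")
    df = df.set_index("feature_id")
    class_of = None
    if "class" in df.columns:
        class_of = df.pop("class").astype(str)
    return FeatureTable(layer=layer, values=df, design=design, class_of=class_of)


def write_stage_table(table: FeatureTable, path) -> None:
    out = table.values.copy()
    if table.class_of is not None:
        out.insert(0, "class", table.class_of.reindex(out.index))
    out.to_csv(path, sep="\t", index_label="feature_id", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# gene models and promoters


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id}: strand must be '+' or '-'")


def read_gene_annotation(path) -> list[GeneModel]:
    """Read gene models from BED6 (chrom, start, end, name, score, strand)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise InputError(f"{path}:{ln}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = parts[:6]
            if name in seen:
                raise InputError(f"{path}:{ln}: duplicate gene name {name!r}")
            seen.add(name)
            genes.append(GeneModel(name, chrom, int(start), int(end), strand))
    return genes


def write_gene_annotation(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\n")


def promoter_interval(
    gene: GeneModel, upstream_bp: int = 2000, chrom_length: int | None = None
) -> tuple[str, int, int]:
    """Strand-aware promoter window immediately upstream of the 5' end.

    Half-open, clipped at the chromosome start (and end, when the length is
    known). Never overlaps the gene body and has length <= upstream_bp.
    """
    if upstream_bp <= 0:
        raise InputError("upstream_bp must be positive")
    if gene.strand == "+":
        return gene.chrom, max(0, gene.start - upstream_bp), gene.start
    end = gene.end + upstream_bp
    if chrom_length is not None:
        end = min(end, chrom_length)
    return gene.chrom, gene.end, end


def promoter_table(
    genes: list[GeneModel], upstream_bp: int = 2000, chrom_length: int | None = None
) -> pd.DataFrame:
    """Promoter intervals of all genes as a DataFrame (gene-indexed)."""
    rows = [promoter_interval(g, upstream_bp, chrom_length) for g in genes]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"],
                        index=pd.Index([g.gene_id for g in genes], name="gene_id"))


# ---------------------------------------------------------------------------
# methylation


def read_cytosine_report(path, sample_id: tuple[str, int] | None = None) -> pd.DataFrame:
    """Parse a Bismark-style cytosine report into a per-site DataFrame.

    Input lines: chrom, 1-based position, strand, methylated count,
    unmethylated count, context, trinucleotide (whitespace separated).
    Output columns: chrom, pos (0-based), strand, context, meth, unmeth,
    level (NaN at zero coverage). ``sample_id`` is stored in ``df.attrs``.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"],
        dtype={"chrom": str, "strand": str, "context": str, "tri": str},
    )
    for col in ("pos", "meth", "unmeth"):
        as_num = pd.to_numeric(df[col], errors="coerce")
        if as_num.isna().any() or (as_num % 1 != 0).any():
            raise InputError(f"{path}: non-integer value in column {col!r}")
        df[col] = as_num.astype(np.int64)
    if (df["pos"] < 1).any():
        raise InputError(f"{path}: positions must be 1-based (>= 1)")
    if (df[["meth", "unmeth"]].to_numpy() < 0).any():
        raise InputError(f"{path}: negative methylation count")
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise InputError(
            f"{path}: invalid context {df.loc[bad, 'context'].iloc[0]!r}"
        )
    df["pos"] = df["pos"] - 1
    cov = df["meth"] + df["unmeth"]
    with np.errstate(invalid="ignore"):
        df["level"] = np.where(cov > 0, df["meth"] / cov.replace(0, np.nan), np.nan)
    df = df.drop(columns="tri")
    df.attrs["sample_id"] = sample_id
    return df


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    """Write sites back to the 1-based cytosine-report dialect."""
    out = df[["chrom", "pos", "strand", "meth", "unmeth", "context"]].copy()
    out["pos"] = out["pos"] + 1
    out["tri"] = out["context"].map(_TRINUCLEOTIDE)
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class Methylome:
    """Cytosine methylation of one experiment: shared sites x all samples.

    ``sites`` holds chrom / pos (0-based) / strand / context, identical across
    samples; ``meth`` and ``total`` are (n_sites, n_samples) count matrices in
    ``design.sample_ids()`` order. Pooling across replicates or stages is a
    column sum, which keeps every level a ratio of summed counts.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    design: StageDesign = field(default_factory=StageDesign)

    def __post_init__(self) -> None:
        n = len(self.sites)
        n_samples = len(self.design.sample_ids())
        if self.meth.shape != (n, n_samples) or self.total.shape != (n, n_samples):
            raise InputError("methylation count matrices do not match sites x samples")
        if (self.meth < 0).any() or (self.total < self.meth).any():
            raise InputError("methylation counts must satisfy 0 <= meth <= total")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_columns(self, stage: str | None = None) -> np.ndarray:
        ids = self.design.sample_ids()
        if stage is None:
            return np.arange(len(ids))
        if stage not in self.design.stages:
            raise InputError(f"unknown stage {stage!r}")
        return np.array([i for i, (s, _) in enumerate(ids) if s == stage])

    def stage_counts(self, stage: str) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-pooled (meth, total) count vectors for one stage."""
        cols = self.sample_columns(stage)
        return self.meth[:, cols].sum(axis=1), self.total[:, cols].sum(axis=1)

    def context_mask(self, context: str | None) -> np.ndarray:
        if context is None:
            return np.ones(self.n_sites, dtype=bool)
        if context not in CONTEXTS:
            raise InputError(f"unknown context {context!r}")
        return (self.sites["context"] == context).to_numpy()

    def to_reports(self, out_dir, prefix: str = "cytosine") -> list[str]:
        """Write one cytosine report per sample; returns the file paths."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for j, (stage, rep) in enumerate(self.design.sample_ids()):
            df = self.sites.copy()
            df["meth"] = self.meth[:, j]
            df["unmeth"] = self.total[:, j] - self.meth[:, j]
            path = out_dir / f"{prefix}_{stage}_R{rep}.txt"
            write_cytosine_report(df, path)
            paths.append(str(path))
        return paths

    @classmethod
    def from_reports(cls, paths: dict[tuple[str, int], str],
                     design: StageDesign | None = None) -> "Methylome":
        """Assemble a Methylome from per-sample cytosine reports.

        All reports must describe the same site set in the same order.
        """
        design = design or StageDesign()
        ids = design.sample_ids()
        missing = [s for s in ids if s not in paths]
        if missing:
            raise InputError(f"missing cytosine reports for samples {missing}")
        sites = None
        meth = []
        total = []
        for sid in ids:
            df = read_cytosine_report(paths[sid], sample_id=sid)
            key = df[["chrom", "pos", "strand", "context"]]
            if sites is None:
                sites = key.reset_index(drop=True)
            elif not key.reset_index(drop=True).equals(sites):
                raise InputError(f"cytosine report for {sid} has a different site set")
            meth.append(df["meth"].to_numpy())
            total.append((df["meth"] + df["unmeth"]).to_numpy())
        return cls(sites=sites, meth=np.column_stack(meth),
                   total=np.column_stack(total), design=design)


# ---------------------------------------------------------------------------
# 24-nt siRNA clusters


def read_sirna_clusters(path, design: StageDesign | None = None) -> pd.DataFrame:
    """Read a 24-nt siRNA cluster table (BED-like + per-sample read counts).

    Columns: chrom, start, end, name, then one count column per sample
    named ``<stage>_R<k>``.
    """
    design = design or StageDesign()
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "name"]
    for col in required:
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    expected = design.columns()
    missing = set(expected) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing sample columns {sorted(missing)}")
    if (df["start"] >= df["end"]).any():
        raise InputError(f"{path}: cluster with start >= end")
    if (df[expected].to_numpy() < 0).any():
        raise InputError(f"{path}: negative read count")
    return df[required + expected]


def write_sirna_clusters(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
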