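import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import stageomics as so
from stageomics.design import StageDesign

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_feature_table(values, layer="metabolome", design=None, ids=None,
                       class_of=None) -> so.FeatureTable:
    """Build a FeatureTable from a (features x samples) array."""
    design = design or StageDesign()
    values = np.asarray(values, dtype=float)
    ids = ids if ids is not None else [f"f{i + 1}" for i in range(len(values))]
    df = pd.DataFrame(values, index=pd.Index(ids, name="feature_id"),
                      columns=design.columns())
    cls = pd.Series(class_of, index=ids) if class_of is not None else None
    return so.FeatureTable(layer=layer, values=df, design=design, class_of=cls)


def toy_methylome(pos, context, meth, total, design, chrom="ChrT") -> so.Methylome:
    """Methylome from explicit per-site/per-sample count matrices."""
    pos = np.asarray(pos)
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "strand": "+",
        "context": context if not isinstance(context, str)
        else [context] * len(pos),
    })
    return so.Methylome(sites=sites, meth=np.asarray(meth, dtype=np.int64),
                        total=np.asarray(total, dtype=np.int64), design=design)


@pytest.fixture(scope="session")
def default_dataset() -> so.SimulatedDataset:
    """The reference synthetic study at its default size (seed 1)."""
    return so.simulate_multiomics(so.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline run on the default synthetic study (seed 1)."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    manifest = so.run_pipeline(so.PipelineConfig(seed=1), out)
    return manifest, out


@pytest.fixture(scope="session")
def small_dataset() -> so.SimulatedDataset:
    cfg = so.SimulationConfig(
        seed=7, n_metabolites=60, n_genes=300, n_proteins=120,
        n_planted_edges=40, n_planted_dmrs=15, n_coupled_promoters=15,
        sirna_background_clusters=40,
    )
    return so.simulate_multiomics(cfg)
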