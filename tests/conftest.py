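import numpy as np
import pandas as pd
import pytest

from epinstab.io import ExpressionMatrix, SampleSheet
from epinstab.pipeline import PipelineConfig, run_all
from epinstab.simulate import SimulationConfig

#: the consensus edges planted by the default driver panel
PLANTED_EDGES = {("UHRF1", "HyperZ", 1), ("WHSC1", "HyperZ", 1), ("CBX7", "HypoZ", -1)}


def make_sheet(normals, cancers, cohort="c1"):
    ids = list(normals) + list(cancers)
    return SampleSheet(
        pd.DataFrame(
            {
                "status": ["normal"] * len(normals) + ["cancer"] * len(cancers),
                "cohort_id": cohort,
                "group": "",
            },
            index=pd.Index(ids, name="sample_id"),
        )
    )


def make_expr(values, genes, samples, scale="log2", cohort="c1"):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples),
        scale=scale,
        cohort_id=cohort,
    )


@pytest.fixture(scope="session")
def default_run():
    """One full default 10-cohort pipeline run (seed 0), shared read-only."""
    return run_all(PipelineConfig(sim=SimulationConfig(seed=0)))


@pytest.fixture(scope="session")
def small_study_config():
    """A reduced study for fast end-to-end exercises."""
    return SimulationConfig(
        n_cohorts=2,
        n_normal=10,
        n_cancer=40,
        n_genes=60,
        n_ee_genes=10,
        n_cgi_regions=40,
        n_opensea_regions=40,
        seed=7,
    )
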