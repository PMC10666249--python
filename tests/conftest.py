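import numpy as np
import pytest

from sarscape.curation import clean_records
from sarscape.pipeline import PipelineConfig, run_all
from sarscape.synthetic import emulate_study_shape


@pytest.fixture(scope="session")
def study_dataset():
    """The 549-compound study-shaped synthetic dataset (seed 42)."""
    records, truth = emulate_study_shape(seed=42)
    return records, truth


@pytest.fixture(scope="session")
def study_curated(study_dataset):
    records, _ = study_dataset
    return clean_records(records)


@pytest.fixture(scope="session")
def pipeline_bundle(tmp_path_factory):
    """One full pipeline run on the study-shaped dataset (reduced model set
    to keep the suite fast; determinism and artifact structure are what the
    dependent tests check)."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = PipelineConfig(
        out_dir=str(out),
        algorithms=["extra_trees"],
        cv_folds=5,
        n_estimators=100,
        ad_scaffold_gate=True,
    )
    manifest = run_all(cfg)
    return cfg, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
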