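import numpy as np
import pytest

from methylotrace import pipeline, synthetic_data


@pytest.fixture(scope="session")
def promoter():
    """Default synthetic promoter: (sequence, catalog with regions)."""
    seq, catalog = synthetic_data.make_promoter_sequence(seed=42)
    return seq, synthetic_data.assign_regions(catalog)


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """One full simulated pipeline run (small molecule pool for speed)."""
    outdir = tmp_path_factory.mktemp("cohort")
    cfg = pipeline.RunConfig(seed=11, n_molecules=1500)
    results = pipeline.run_all(cfg, outdir)
    return cfg, outdir, results


@pytest.fixture()
def rng():
    return np.random.default_rng(0)

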