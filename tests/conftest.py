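import numpy as np
import pytest

from ncxtalk.fixtures import reference_tables, synthetic_signature_bridge
from ncxtalk.pipeline import PipelineConfig
from ncxtalk.simulate import SimulationConfig, write_bundle


@pytest.fixture(scope="session")
def fixtures_bundle():
    return reference_tables()


@pytest.fixture(scope="session")
def signature_bridge():
    return synthetic_signature_bridge()


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """Default-condition synthetic bundle plus its planted ground truth."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = write_bundle(SimulationConfig(seed=11), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def synthetic_run(synthetic_bundle, tmp_path_factory):
    """Full pipeline run over the default synthetic bundle."""
    from ncxtalk.pipeline import run_all

    outdir, truth = synthetic_bundle
    results = tmp_path_factory.mktemp("results")
    config = PipelineConfig(
        out_dir=str(results),
        gwas_a=[str(outdir / "gwas_a.tsv")],
        gwas_b=[str(outdir / "gwas_b.tsv")],
        ld_pairs=str(outdir / "ld_pairs.tsv"),
        annotation=str(outdir / "annotation.tsv"),
        interactions_pm=str(outdir / "interactions_pm.tsv"),
        interactions_ml=str(outdir / "interactions_ml.tsv"),
    )
    summary = run_all(config)
    return results, truth, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
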