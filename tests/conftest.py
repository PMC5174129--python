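from pathlib import Path

import pytest

import droughtmine as dm

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_config() -> dm.AnalysisConfig:
    return dm.AnalysisConfig()


@pytest.fixture(scope="session")
def default_bundle() -> dm.Bundle:
    """Full-size synthetic study (2000 genes, 120 metabolites), seed 1."""
    return dm.generate_dataset(dm.SimulationSpec(rng_seed=1))


@pytest.fixture(scope="session")
def worked_bundle() -> dm.Bundle:
    """The miniature hand-auditable bundle (20 genes, 10 metabolites)."""
    return dm.make_worked_fixture()


@pytest.fixture(scope="session")
def worked_fixture_dir() -> Path:
    return DATA_DIR / "worked_fixture"


@pytest.fixture(scope="session")
def worked_results(worked_bundle, default_config, tmp_path_factory):
    """Full pipeline results on the worked fixture."""
    d = tmp_path_factory.mktemp("worked")
    paths = dm.write_bundle(worked_bundle, d)
    return dm.run_pipeline(default_config, paths, d / "out")


@pytest.fixture(scope="session")
def small_bundle() -> dm.Bundle:
    """Mid-size bundle for module-level recovery checks."""
    spec = dm.SimulationSpec(
        n_genes=400, n_metabolites=30, n_key_metabolites=4, n_candidate_genes=4,
        n_single_genotype_metabolites=3, rng_seed=7,
    )
    return dm.generate_dataset(spec)
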