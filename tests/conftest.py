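import numpy as np
import pytest

import depotsim as ds


@pytest.fixture(scope="session")
def paper_bundle() -> ds.ParameterBundle:
    """The packaged bupivacaine liposome-alginate parameter file."""
    return ds.packaged_parameters()


@pytest.fixture(scope="session")
def viability_table() -> ds.ViabilityTable:
    return ds.ViabilityTable.packaged()


@pytest.fixture(scope="session")
def paper_run(paper_bundle) -> ds.SimulationResult:
    """One forward run of the packaged 1 mM liposome-alginate construct."""
    b = paper_bundle
    return ds.simulate_release(b.geometry, b.drug, b.construct, b.config)


@pytest.fixture(scope="session")
def noiseless_curve(paper_bundle) -> ds.ReleaseCurve:
    from depotsim.synthetic_data import ReleaseGenSpec, generate_release_data
    b = paper_bundle
    return generate_release_data(ReleaseGenSpec(
        noise_model="none", geometry=b.geometry, drug=b.drug,
        construct=b.construct))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160802)
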