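import numpy as np
import pytest

import protonbeam as pb


@pytest.fixture(scope="session")
def water():
    return pb.get_medium("water")


@pytest.fixture(scope="session")
def window150():
    return pb.EnergyWindow(0.1, 150.0)


@pytest.fixture(scope="session")
def spectrum_1pct(window150):
    """The benchmark inflow beam: 62 MeV, 1% spread, 1.21e9 protons/cm^2."""
    return pb.make_gaussian_spectrum(62.0, 0.01, 1.21e9, window150)


@pytest.fixture(scope="session")
def field_1pct(water, spectrum_1pct):
    return pb.FluenceField(water, spectrum_1pct)


@pytest.fixture(scope="session")
def narrow_field(water, window150):
    """Quasi-monoenergetic beam (0.01% spread) for delta-limit oracles."""
    spec = pb.make_gaussian_spectrum(62.0, 1e-4, 1.21e9, window150)
    return pb.FluenceField(water, spec)


@pytest.fixture(scope="session")
def example_basis(water, window150):
    """30 basis beams, unit variance, ranges equally spaced on [3, 6.25] cm."""
    return pb.select_basis_energies(30, (3.0, 6.25), 1.0, water, window150)


@pytest.fixture(scope="session")
def tumour_regions():
    return pb.RegionPartition(tumour=(3.0, 6.0))


@pytest.fixture(scope="session")
def example1_plan(example_basis, tumour_regions, water, window150):
    return pb.TreatmentPlan(example_basis, tumour_regions, water,
                            target=1.0, weights=(1.0, 0.0, 0.0),
                            window=window150)


@pytest.fixture(scope="session")
def example1_results(example1_plan):
    return example1_plan.fit(method="quasi_newton")


@pytest.fixture(scope="session")
def example2_plan(example_basis, water, window150):
    regions = pb.RegionPartition(tumour=(3.0, 6.0), oar=(6.0, 8.0))
    return pb.TreatmentPlan(example_basis, regions, water, target=1.0,
                            weights=(1.0, 10.0, 0.0), window=window150)


@pytest.fixture(scope="session")
def empirical_dist(water):
    return pb.ParameterDistribution.from_case("empirical", water)
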