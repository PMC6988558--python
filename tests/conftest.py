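import pytest

from marshbn import (CaseFile, CovariateDef, ResponseSpec, SimConfig, TrapCase,
                     fit_schemes, simulate, to_model_cases)


@pytest.fixture(scope="session")
def survey():
    """Full-scale synthetic survey: 12,405 trap nights, default conditions."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def captures(survey):
    return to_model_cases(survey, ResponseSpec.rera_presence())


@pytest.fixture(scope="session")
def captures_all(survey):
    return to_model_cases(survey, ResponseSpec.all_species())


@pytest.fixture(scope="session")
def schemes(captures):
    return fit_schemes(captures)


@pytest.fixture(scope="session")
def small_survey():
    """Small survey for structure-learning and CV tests."""
    return simulate(SimConfig(n_sites=3, traps_per_site=250, nights=3, seed=5))


def make_tiny_casefile():
    catalog = [
        CovariateDef("Dist_Road", units="m"),
        CovariateDef("Patch_Size", units="ha"),
    ]
    cases = [
        TrapCase("A", 2000, "spring", "grid", 38.1, -122.4, "RERA",
                 {"Dist_Road": 1500.0, "Patch_Size": 30.0}),
        TrapCase("A", 2000, "spring", "grid", 38.1, -122.4, "TRAP",
                 {"Dist_Road": 200.0}),
        TrapCase("B", 2001, "summer", "transect", 38.2, -122.3, "MICA",
                 {"Patch_Size": 5.0}),
    ]
    return CaseFile(cases=cases, catalog=catalog)


@pytest.fixture()
def tiny_casefile():
    return make_tiny_casefile()
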