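import pandas as pd
import pytest
from hypothesis import settings

import mosqsurv as ms

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_scenario() -> ms.CountScenario:
    """Two-species survey small enough for repeated fitting in tests."""
    return ms.CountScenario(
        seed=42,
        n_sites=10,
        n_months=10,
        n_species=2,
        species=("Aedes_aegypti", "Aedes_taeniorhynchus"),
        m_trait=(False, True),
        beta4=(0.2, -1.35),
        beta5=(0.13, -2.11),
        beta6=(-0.43, -1.21),
        phi=5.0,
        n_rare_species=0,
        genus_only_fraction=0.0,
    )


@pytest.fixture(scope="session")
def small_survey(small_scenario):
    sites = ms.generate_sites(small_scenario)
    precip = ms.generate_precip(small_scenario)
    traits = ms.generate_traits(small_scenario)
    table, truth = ms.generate_count_data(small_scenario, sites, precip, traits)
    return {
        "scenario": small_scenario,
        "sites": sites,
        "precip": precip,
        "precip_std": ms.standardize_precip(precip),
        "traits": traits,
        "table": table,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def survey_scenario() -> ms.CountScenario:
    """Full survey-scale scenario at the generator defaults."""
    return ms.CountScenario(seed=7)


@pytest.fixture(scope="session")
def survey(survey_scenario):
    sites = ms.generate_sites(survey_scenario)
    precip = ms.generate_precip(survey_scenario)
    traits = ms.generate_traits(survey_scenario)
    table, truth = ms.generate_count_data(survey_scenario, sites, precip, traits)
    return {
        "scenario": survey_scenario,
        "sites": sites,
        "precip": precip,
        "precip_std": ms.standardize_precip(precip),
        "traits": traits,
        "table": table,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_fit(small_survey):
    """A converged H2 fit on the two-species survey, reused across tests."""
    specs = {s.name: s for s in ms.build_candidate_set(
        sorted(small_survey["scenario"].species), small_survey["traits"])}
    mats = ms.design_matrices(
        specs["H2"],
        small_survey["table"],
        small_survey["sites"],
        small_survey["precip_std"],
        small_survey["traits"],
    )
    return ms.NegBinomMixedModel(specs["H2"], mats).fit(restarts=1, seed=0)


def make_count_table(rows) -> ms.CountTable:
    return ms.CountTable(
        pd.DataFrame(rows, columns=["site_id", "month_index", "species", "count", "genus_only"])
    )
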