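"""Shared fixtures: one synthetic study and a few fitted posteriors.

The expensive MCMC fits are session-scoped so that structural checks,
convergence checks and effect summaries all reuse the same draws.
"""

import numpy as np
import pytest

import creelweather as cw
from creelweather import prep

DESK_SPEC = dict(chains=3, iterations=4000, burnin=2000, thin=1)


@pytest.fixture(scope="session")
def dataset():
    """Default full synthetic study: storms, pandemic year, observation noise."""
    return cw.simulate_dataset(42)


@pytest.fixture(scope="session")
def weekly_records(dataset):
    region_effort = prep.aggregate_regions(dataset.effort_by_area)
    adv = prep.realign_warning_weeks(dataset.advisories, dataset.storms)
    return prep.assemble_weekly_records(region_effort, dataset.weekly_weather, adv)


@pytest.fixture(scope="session")
def retained_records(weekly_records):
    retained, _ = prep.exclusion_filter(weekly_records)
    return retained


@pytest.fixture(scope="session")
def quiet_dataset():
    """364 weeks per region from the known truth with storms and pandemic off."""
    return cw.simulate_dataset(202, truth=cw.TruthBundle.default().quiet(),
                               storms=[])


@pytest.fixture(scope="session")
def quiet_design_east(quiet_dataset):
    rec = prep.assemble_weekly_records(
        prep.aggregate_regions(quiet_dataset.effort_by_area),
        quiet_dataset.weekly_weather, quiet_dataset.advisories)
    return prep.standardize(rec[rec["region"] == "east"], region="east")


@pytest.fixture(scope="session")
def quiet_posterior(quiet_design_east):
    """Desk-scale fit (3 chains x 4,000) on the undisturbed 364-week design."""
    spec = cw.WeatherModelSpec(**DESK_SPEC)
    model = cw.build_weather_model(quiet_design_east, spec)
    return cw.fit_weather_model(model, spec, seed=7)


@pytest.fixture(scope="session")
def regional_posteriors(retained_records):
    """Desk-scale fits of both regional models on the filtered study data."""
    posteriors = {}
    for i, region in enumerate(("east", "west")):
        design = prep.standardize(
            retained_records[retained_records["region"] == region], region=region)
        spec = cw.WeatherModelSpec(**DESK_SPEC)
        model = cw.build_weather_model(design, spec)
        posteriors[region] = cw.fit_weather_model(model, spec, seed=100 + i)
    return posteriors


@pytest.fixture(scope="session")
def tc_subset(dataset):
    return cw.build_tc_subset(dataset.effort, dataset.storms, dataset.advisories)
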