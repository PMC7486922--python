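import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from maizecast import synth
from maizecast.features import DetrendScheme, attach_detrended_target, build_candidate_features
from maizecast.cube import broadcast_pdsi


@pytest.fixture(scope="session")
def small_world():
    """One state, 2 CRDs x 3 counties, 6 years: panels for fast unit tests."""
    years = list(range(2008, 2014))
    geo = synth.simulate_geography(1, 2, 3, seed=11)
    weather = synth.simulate_weather(geo, years, seed=12)
    soil = synth.simulate_soil(geo, seed=13)
    pdsi = synth.simulate_pdsi(geo, years, seed=14)
    response = synth.ResponseConfig(seed=15)
    yields = synth.simulate_yield(weather, soil, pdsi, response, geo)
    return {
        "geo": geo,
        "years": years,
        "weather": weather,
        "soil": soil,
        "pdsi": pdsi,
        "yields": yields,
        "response": response,
    }


@pytest.fixture(scope="session")
def state_panel():
    """One 5-CRD x 6-county state over 20 years: enough samples for MI/regression."""
    years = list(range(1994, 2014))
    geo = synth.simulate_geography(1, 5, 6, seed=31)
    weather = synth.simulate_weather(geo, years, seed=32)
    soil = synth.simulate_soil(geo, seed=33)
    pdsi = synth.simulate_pdsi(geo, years, seed=34)
    yields = synth.simulate_yield(weather, soil, pdsi, synth.ResponseConfig(seed=35), geo)
    pdsi_daily = broadcast_pdsi(pdsi, geo)
    panel = build_candidate_features(weather, soil, pdsi_daily, geo.corn_ratio)
    attach_detrended_target(panel, yields, DetrendScheme())
    return panel


@pytest.fixture(scope="session")
def small_panel(small_world):
    """28-channel candidate panel with de-trended targets for the small world."""
    w = small_world
    pdsi_daily = broadcast_pdsi(w["pdsi"], w["geo"])
    panel = build_candidate_features(w["weather"], w["soil"], pdsi_daily, w["geo"].corn_ratio)
    attach_detrended_target(panel, w["yields"], DetrendScheme())
    return panel
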