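import pytest

from accessmon.friction import SpeedSet, build_friction
from accessmon.geodata import rasterize_roads
from accessmon.monitor import timeseries
from accessmon.synthdistrict import ScenarioConfig, generate


@pytest.fixture(scope="session")
def district():
    """Default synthetic district (fixed seed), shared across tests."""
    return generate(ScenarioConfig())


@pytest.fixture(scope="session")
def district_classes(district):
    cfg = district.config
    return rasterize_roads(district.roads, cfg.grid, cfg.road_buffer_m)


@pytest.fixture(scope="session")
def district_friction(district_classes):
    return build_friction(district_classes, SpeedSet())


@pytest.fixture(scope="session")
def district_timeseries(district, district_friction):
    return timeseries(district.records, district.villages, district.clinics,
                      district.timeline, district_friction, B=200, seed=7)


@pytest.fixture(scope="session")
def small_config():
    """A compact district for fast end-to-end / CLI runs."""
    return ScenarioConfig(
        seed=42, n_rows=80, n_cols=60, origin_y=8_000.0, trunk_x=4_000.0,
        n_feeder_tracks=3, n_villages=40, n_months=25,
        clinic_opening_months=(0, 6, 14, 14),
    )


@pytest.fixture(scope="session")
def small_district(small_config):
    return generate(small_config)
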