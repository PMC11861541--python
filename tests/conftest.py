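import pytest
from hypothesis import HealthCheck, settings as hyp_settings

hyp_settings.register_profile(
    "pestrisk",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("pestrisk")

from pestrisk import demo_tables, parse_scenario  # noqa: E402

#: The worked-example treatment: the published exercise product on 10 ha of
#: olive grove, open-cockpit tractor, no PPE anywhere, 60 kg operator.
REFERENCE_SCENARIO_TOML = """
[crop]
name = "olive"
height = "high"
pest = "olive fruit fly"
area_ha = 10.0

[product]
name = "KILLER"

[application]
spray_volume_hl_per_ha = 10.0
tank_volume_l = 1000.0
pressure_bar = 3.0
equipment = "tractor_open"

[operator]
body_weight_kg = 60.0
"""


@pytest.fixture(scope="session")
def tables():
    return demo_tables()


@pytest.fixture()
def killer_scenario():
    return parse_scenario(REFERENCE_SCENARIO_TOML)
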