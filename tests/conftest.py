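import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_landscape():
    """A compact archipelago shared across tests (deterministic)."""
    from mangrovemove.synthdata import LandscapeSpec, generate_landscape

    spec = LandscapeSpec(
        extent=(0.0, 0.0, 12_000.0, 12_000.0),
        cell_size=50.0,
        channel_count=5,
        width_range=(30.0, 600.0),
        seed=7,
    )
    raster, channels = generate_landscape(spec)
    return spec, raster, channels


@pytest.fixture(scope="session")
def simulated_tiger(small_landscape):
    """A 30-day default-parameter tiger on the shared landscape."""
    from mangrovemove.synthdata import TigerSimSpec, random_land_point, simulate_tiger

    _, raster, channels = small_landscape
    rng = np.random.default_rng(11)
    home = random_land_point(raster, rng, margin_m=2_000.0)
    spec = TigerSimSpec(home_center=home, duration_days=30, animal_id="T00", seed=5)
    traj, truth = simulate_tiger(spec, (raster, channels))
    return spec, traj, truth
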