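import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import retflim as rf

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def instrument() -> rf.InstrumentModel:
    """Default acquisition model: 12.5 ns period, 256 bins, 0.15 ns IRF."""
    return rf.InstrumentModel()


@pytest.fixture(scope="session")
def fine_instrument() -> rf.InstrumentModel:
    """Finely sampled timing for continuum-limit phasor checks."""
    return rf.InstrumentModel(n_bins=4096)


@pytest.fixture(scope="session")
def phantom() -> rf.LayerLabelMap:
    return rf.make_phantom(600, 300, 1.0, seed=7)


@pytest.fixture(scope="session")
def wide_phantom() -> rf.LayerLabelMap:
    """Vessel-free straight phantom wide enough for all five zones."""
    return rf.make_phantom(3200, 300, 1.0, seed=3, vessels=False)


@pytest.fixture(scope="session")
def hb_field(instrument) -> tuple[rf.LayerLabelMap, rf.PhasorField]:
    """Noiseless calibrated hemoglobin/melanin-channel phasor field."""
    ph = rf.make_phantom(600, 300, 1.0, seed=5)
    cube = rf.simulate_decay_cube(
        ph, instrument, "hb_melanin", 1e4, poisson=False, seed=0
    )
    ref = rf.simulate_reference_cube(instrument, 1.0, poisson=False)
    field = rf.calibrate(rf.phasor_transform(cube), ref, 1.0)
    return ph, field


def calibrated_mono_field(
    instrument: rf.InstrumentModel,
    tau: float,
    harmonic: int = 1,
    ref_tau: float = 1.0,
    photons: float = 1e6,
    poisson: bool = False,
    seed: int = 0,
    shape=(2, 2),
) -> rf.PhasorField:
    """Simulate a uniform mono-exponential cube and calibrate its phasor."""
    cube = rf.simulate_reference_cube(
        instrument, tau, photons, shape=shape, poisson=poisson, seed=seed
    )
    field = rf.phasor_transform(cube, harmonic=harmonic)
    ref = rf.simulate_reference_cube(
        instrument, ref_tau, 1e6, shape=shape, poisson=False
    )
    return rf.calibrate(field, ref, ref_tau, harmonic=harmonic)
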