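import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from altiop import CalibrationTable, load_rabbit_trip, load_rigidity_coefficients

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rabbit_trips():
    """The packaged six-eye road-trip dataset, nine stations per eye."""
    return load_rabbit_trip()


@pytest.fixture(scope="session")
def trips_by_id(rabbit_trips):
    return {s.eye_id: s for s in rabbit_trips}


@pytest.fixture(scope="session")
def coefficients():
    return load_rigidity_coefficients()


@pytest.fixture(scope="session")
def calib_table():
    """Synthetic two-weight Schiötz calibration grid.

    Pressure halves (so log10 P falls linearly) and volume rises as the
    scale reading increases, at both plunger weights, mimicking the
    structure of published calibration tables.
    """
    rows = [
        # weight_g, scale_reading, pressure_mmhg, volume_mm3
        (5.5, 2.0, 40.0, 7.0),
        (5.5, 4.0, 20.0, 10.0),
        (5.5, 6.0, 10.0, 12.0),
        (10.0, 2.0, 80.0, 20.0),
        (10.0, 4.0, 40.0, 25.0),
        (10.0, 6.0, 20.0, 30.0),
    ]
    return CalibrationTable(
        pd.DataFrame(rows, columns=["weight_g", "scale_reading", "pressure_mmhg", "volume_mm3"])
    )
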