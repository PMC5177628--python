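import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nafkit.core import MarkerProfiles, PercentProfile

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def percent_profile(analyte_id, percents):
    """Build a PercentProfile from values (NaN = not detected)."""
    arr = np.asarray(percents, dtype=float)
    return PercentProfile(analyte_id, arr, np.isfinite(arr))


def markers_from_arrays(plastid, cytosol, vacuole):
    return MarkerProfiles(
        {
            "plastid": percent_profile("marker_plastid", plastid),
            "cytosol": percent_profile("marker_cytosol", cytosol),
            "vacuole": percent_profile("marker_vacuole", vacuole),
        }
    )


@pytest.fixture
def tie_markers():
    """Three identical marker profiles: the full-tie regime."""
    flat = [20.0, 20.0, 20.0, 20.0, 20.0]
    return markers_from_arrays(flat, flat, flat)


@pytest.fixture
def separated_markers():
    """Markers whose pairwise slope differences exceed the 10-point bound
    on every fraction pair, so compartments never share hits."""
    return markers_from_arrays(
        [70.0, 20.0, 7.0, 3.0],
        [5.0, 40.0, 45.0, 10.0],
        [2.0, 6.0, 22.0, 70.0],
    )
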