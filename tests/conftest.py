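import numpy as np
import pytest

from larch2s.climate import ClimateSeries
from larch2s.seddna import default_reference
from larch2s.species import default_species_params
from larch2s.synth import KHATANGA_NORMALS_P, KHATANGA_NORMALS_T


@pytest.fixture(scope="session")
def params():
    return default_species_params()


@pytest.fixture(scope="session")
def reference():
    return default_reference()


def constant_series(start, end, tmean=None, prec=None, offset=0.0, label="const"):
    """A noise-free climate series repeating the Khatanga normals."""
    n = end - start + 1
    t = (KHATANGA_NORMALS_T if tmean is None else np.asarray(tmean, dtype=float)) + offset
    p = KHATANGA_NORMALS_P if prec is None else np.asarray(prec, dtype=float)
    return ClimateSeries(
        np.arange(start, end + 1), np.tile(t, (n, 1)), np.tile(p, (n, 1)), label=label
    )


@pytest.fixture
def benign_weather():
    """Warm-summer weather indices: ample growing season."""
    from larch2s.simulator import derive_weather_indices

    return derive_weather_indices(constant_series(0, 0, offset=2.0).year_record(0))
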