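import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon, box

from sioi.io_core import PipelineConfig


@pytest.fixture
def square_case():
    """2000x2000 um square tumor whose top edge is the invasive front.

    Analytic areas (mm^2): IM (clipped to tissue spanning 500 um beyond the
    front) = 2.0; IM inside tumor = 1.0; CT = 3.0; TBROI = 2.0.
    """
    tumor = Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)])
    front = LineString([(0, 0), (2000, 0)])
    tissue = box(0, -500, 2000, 2000)
    return tumor, front, tissue


@pytest.fixture
def toy_survival():
    """Five subjects, times 1..5, events 1,1,0,1,0 -> S(4+) = 0.3."""
    return pd.DataFrame(
        {"time_months": [1.0, 2.0, 3.0, 4.0, 5.0], "event": [1, 1, 0, 1, 0]}
    )


@pytest.fixture
def default_config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
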