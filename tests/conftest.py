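import numpy as np
import pytest

from oxyhb.io import Condition, OECSeries
from oxyhb.mwc import MWCParameters


@pytest.fixture
def cond37():
    """Stripped condition at pH 7.2, 37 C."""
    return Condition.from_celsius(ph=7.2, temp_c=37.0)


@pytest.fixture
def adult_params():
    """Generic adult-like MWC parameter set (uncalibrated)."""
    return MWCParameters(
        l0=1.0e5, kr=0.18, kt=55.0,
        dpg_kt=5.0e-5, dpg_kr=1.0e-3,
        cl_kt=0.06, cl_kr=0.15,
        pka_t=7.6, pka_r=6.5,
    )


def hill_series(p50, n50, po2, sample_id="synthetic", condition=None, noise=None):
    """Series drawn exactly from a two-parameter Hill curve, optional noise."""
    condition = condition or Condition.from_celsius(ph=7.2, temp_c=37.0)
    po2 = np.asarray(po2, dtype=float)
    sat = po2**n50 / (po2**n50 + p50**n50)
    if noise is not None:
        sat = np.clip(sat + noise, 1e-6, 1 - 1e-6)
    return OECSeries(
        sample_id=sample_id,
        condition=condition,
        po2=tuple(po2),
        saturation=tuple(sat),
    )
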