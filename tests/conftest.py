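import numpy as np
import pytest

from glucagon_idms import builtin_species
from glucagon_idms.kinetics import (
    InfusionProtocol,
    InfusionSegment,
    PlasmaTimeSeries,
)


@pytest.fixture(scope="session")
def species():
    """The four built-in glucagon species keyed by name."""
    return {sp.name: sp for sp in builtin_species()}


@pytest.fixture
def steady_state_series():
    """Constant-concentration plasma series: TTR = 0.05 everywhere."""
    n = 6
    return PlasmaTimeSeries(
        time_min=np.arange(n, dtype=float) * 10.0,
        c_ff_pg_ml=np.full(n, 5.0),
        c_ffla_pg_ml=np.full(n, 5.0),
        c_total_pg_ml=np.full(n, 100.0),
    )


@pytest.fixture
def dual_infusion_protocol():
    """Both tracers infused at 1 pg/kg/min for 100 min."""
    seg = (InfusionSegment(0.0, 100.0, 1.0),)
    return InfusionProtocol(f_ff=seg, f_ffla=seg, tbw_kg=70.0)
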