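import numpy as np
import pytest

from bimanual.hkb import HKBParams
from bimanual.synth import DesignSpec, LoadType, Mode


@pytest.fixture
def symmetric_params() -> HKBParams:
    """Canonical symmetric landscape: wells at 0 and pi, a = b = 1."""
    return HKBParams(a=1.0, b=1.0, delta_omega=0.0)


@pytest.fixture
def tiny_design() -> DesignSpec:
    """A fast design: 1 cycle, 2 load pairs, 1 repetition, coarse sampling."""
    return DesignSpec(
        modes=(Mode.IN_PHASE, Mode.ANTI_PHASE),
        cycles_ms=(750.0,),
        load_pairs=((LoadType.NONE, LoadType.NONE), (LoadType.VISCOUS, LoadType.NONE)),
        repetitions=1,
        fs=250.0,
        measurement_noise_m=0.0,
    )


@pytest.fixture
def time_1khz_45s() -> np.ndarray:
    return np.arange(45_000) / 1000.0
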