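import pytest

from standalloc.core import PoolState, TurnoverVector


@pytest.fixture
def evergreen_turnover() -> TurnoverVector:
    """Conifer-like lifespans: foliage ~2 yr, wood ~125 yr, roots ~3.6 yr."""
    return TurnoverVector(u_f=0.5, u_w=0.008, u_r=0.28)


@pytest.fixture
def deciduous_turnover() -> TurnoverVector:
    """Broadleaf-like: foliage replaced annually, wood ~200 yr, roots ~0.9 yr."""
    return TurnoverVector(u_f=1.0, u_w=0.005, u_r=1.1)


@pytest.fixture
def closed_stand() -> PoolState:
    return PoolState(B_f=0.30, B_w=6.0, B_r=0.20)
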