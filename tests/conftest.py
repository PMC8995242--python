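import numpy as np
import pytest

from blochkwic import SequenceParams, TissueParams, build_pattern


@pytest.fixture(scope="session")
def myo_seq():
    """In vivo style protocol: TR 5 ms, t_rec 1.5 s, t_SL 4..60 ms."""
    return SequenceParams()


@pytest.fixture(scope="session")
def myo_tissue():
    return TissueParams(T1=1400.0, T1rho0=40.0)


@pytest.fixture(scope="session")
def phantom_seq():
    """Phantom protocol: fixed 5 s recovery, t_SL 4..102 ms, 128 matrix."""
    return SequenceParams(
        TR=5.0,
        t_rec=5000.0,
        alpha=40.0,
        NR=4,
        t_SL_list=np.linspace(4.0, 102.0, 8),
        f_SL_list=(1500.0,),
        matrix=128,
        fov=38.4,
    )


@pytest.fixture(scope="session")
def tiny_seq():
    """Down-scaled protocol for cheap reconstruction tests."""
    return SequenceParams(
        t_SL_list=(4.0, 40.0),
        NR=2,
        matrix=16,
        fov=16.0,
        f_SL_list=(1500.0,),
    )


@pytest.fixture(scope="session")
def tiny_pattern(tiny_seq, myo_tissue):
    return build_pattern(tiny_seq, myo_tissue, 1500.0, mode="bloch")


@pytest.fixture(scope="session")
def std_pattern(phantom_seq):
    """The 104-preparation / 416-spoke pattern of one relaxation map."""
    prior = TissueParams(T1=1400.0, T1rho0=49.3, m1rho=7.9)
    return build_pattern(phantom_seq, prior, 1500.0, mode="bloch")
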