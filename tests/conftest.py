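import numpy as np
import pytest

from lfpcoupling import Recording, SimConfig, generate_coupled_lfp

FS = 1000.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


@pytest.fixture(scope="session")
def sine8_32s() -> np.ndarray:
    """32 s unit-amplitude 8 Hz sine at 1 kHz (theta-band reference tone)."""
    t = np.arange(int(32 * FS)) / FS
    return np.sin(2 * np.pi * 8.0 * t)


@pytest.fixture(scope="session")
def coupled_60s() -> Recording:
    """60 s strongly coupled (kappa=0.8) default-config recording."""
    return generate_coupled_lfp(
        SimConfig(duration_s=60.0, coupling_strength=0.8, seed=7)
    )


def make_recording(x: np.ndarray, fs: float = FS) -> Recording:
    return Recording(data=np.atleast_2d(x), fs=fs)
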