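import numpy as np
import pytest

from sarsyn import ReceptorKernel, SARParams


@pytest.fixture
def fs_pc_params() -> SARParams:
    """Fast-spiking -> pyramidal reference parameter set (facilitating
    asynchronous pathway on top of a depressing synchronous one)."""
    return SARParams(
        tau_sr=2.0, U_sr=0.3, tau_ar=12.0, U_ar=0.005,
        U_max=0.5, tau_d=30.0, N_F=271, x0=1.0,
    )


@pytest.fixture
def kernel() -> ReceptorKernel:
    """FS->PC GABA-A kernel, quantal amplitude A*x0 = 10 pA for x0 = 1."""
    return ReceptorKernel(tau_syn=5.0, A=10.0, D=0.0)


@pytest.fixture
def spikes_100hz() -> np.ndarray:
    return 10.0 * np.arange(5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
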