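import numpy as np
import pytest

import spc_rheoflow as sr
from spc_rheoflow import synthetic


@pytest.fixture
def maxwell_sweep():
    """Noiseless single-mode Maxwell sweep with the SPC_0 reference
    parameters (eta0 = 5112 Pa·s, lambda = 1.0 s)."""
    return sr.make_saos_sweep(sr.SweepSpec(
        model_kind="maxwell",
        omega_grid=synthetic.default_omega_grid(0.01, 100.0, 50),
        eta0=5112.0, lam=1.0))


@pytest.fixture
def nonlinear_cycle():
    """Noiseless waveform with known third-order Chebyshev content."""
    spec = sr.WaveformSpec(gamma0=1.0, omega=1.0,
                           e_coeffs={1: 100.0, 3: 10.0},
                           v_coeffs={1: 50.0, 3: -5.0})
    return sr.make_laos_waveform(spec), spec


@pytest.fixture
def spc0_material():
    from spc_rheoflow import io
    return io.material_for_sample("SPC_0")


@pytest.fixture
def spc0_ptt():
    from spc_rheoflow import io
    return io.ptt_for_sample("SPC_0")
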