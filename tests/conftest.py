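import numpy as np
import pytest

from osmofit import GrowthSimParams, simulate_growth_curve


@pytest.fixture
def gompertz_params():
    """Noise-free Gompertz parameters with a 0.82 h⁻¹ maximum specific rate."""
    return GrowthSimParams(A=0.5, mu_max=0.82, lag=2.0, t_end=24.0, dt=0.25,
                           noise_cv=0.0)


@pytest.fixture
def gompertz_curve(gompertz_params):
    return simulate_growth_curve(gompertz_params)


@pytest.fixture
def exponential_curve():
    """Exact exponential at 0.5 h⁻¹ starting above the OD floor."""
    from osmofit import GrowthCurve
    t = np.linspace(0.0, 6.0, 61)
    return GrowthCurve(time=t, od=0.01 * np.exp(0.5 * t))
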