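"""Shared fixtures: printed parameter sets and an independent ODE oracle."""

import numpy as np
import pytest

from scrlti import GaussianBurstParams, ScrfParams

# Published parameter sets for the third-order response function:
# recording experiment (aversive / oddball averages) and stimulation
# experiment (low / medium stimulation rate).
THETA_AVERSIVE = ScrfParams(1.3277, 1.1205, 0.1084, -0.4265)
THETA_ODDBALL = ScrfParams(1.5457, 1.9595, 0.1336, 0.3001)
THETA_LOW_RATE = ScrfParams(2.3051, 2.5653, 0.1517, -0.0058)
THETA_MEDIUM_RATE = ScrfParams(2.2433, 4.2898, 0.5584, -0.1775)

BURST_AVERSIVE = GaussianBurstParams(A=0.7814, mu=1.6850, sigma=0.3051, c=0.1567)
BURST_ODDBALL = GaussianBurstParams(A=0.6589, mu=1.6785, sigma=0.2471, c=0.0)

ALL_PRINTED_THETAS = [THETA_AVERSIVE, THETA_ODDBALL, THETA_LOW_RATE, THETA_MEDIUM_RATE]


@pytest.fixture
def theta_low_rate():
    return THETA_LOW_RATE


@pytest.fixture
def burst_aversive():
    return BURST_AVERSIVE


@pytest.fixture
def burst_oddball():
    return BURST_ODDBALL


def naive_rk4_scrf(theta, u, rate, gain, substeps=10):
    """Reference solver: plain Python RK4 loop for the response-function ODE
    x''' = -th1 x'' - th2 x' - th3 x - g*u(t - th4), zero initial conditions,
    linear input interpolation.  Independent of the package's vectorized
    implementation."""
    th1, th2, th3, th4 = theta.as_tuple()
    u = np.asarray(u, float)
    n = len(u)
    dt = 1.0 / rate
    h = dt / substeps
    t_data = np.arange(n) * dt
    t_fine = np.arange((n - 1) * substeps + 1) * h
    u_fine = np.interp(t_fine - th4, t_data, u)
    A = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [-th3, -th2, -th1]])
    E = np.array([0.0, 0.0, -gain])
    y = np.zeros(3)
    out = np.zeros(n)
    k = 0
    for i in range((n - 1) * substeps):
        u0, u1 = u_fine[i], u_fine[i + 1]
        um = 0.5 * (u0 + u1)
        k1 = A @ y + E * u0
        k2 = A @ (y + h / 2 * k1) + E * um
        k3 = A @ (y + h / 2 * k2) + E * um
        k4 = A @ (y + h * k3) + E * u1
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if (i + 1) % substeps == 0:
            k += 1
            out[k] = y[0]
    return out


def random_stable_theta(rng):
    """Draw a random Routh–Hurwitz-stable parameter set."""
    while True:
        th1 = rng.uniform(0.5, 4.0)
        th2 = rng.uniform(0.5, 6.0)
        th3 = rng.uniform(0.02, 1.5)
        th4 = rng.uniform(-1.0, 1.0)
        if th1 * th2 > th3:
            return ScrfParams(th1, th2, th3, th4)


def random_burst_train(rng, rate=10.0, duration=60.0, n_events=None):
    """A random Gaussian burst train on [5, duration-15) seconds."""
    from scrlti import InputTrain, build_input_train

    n_events = n_events or int(rng.integers(2, 6))
    onsets = np.sort(rng.uniform(5.0, duration - 15.0, n_events))
    while np.any(np.diff(onsets) < 0.5):
        onsets = np.sort(rng.uniform(5.0, duration - 15.0, n_events))
    amps = tuple(rng.uniform(0.5, 2.0, n_events))
    return build_input_train(
        InputTrain(tuple(onsets), sigma_in=0.3, amplitudes=amps),
        rate=rate,
        duration=duration,
    )
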