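"""Forward model: Gaussian sudomotor bursts and the ODE response function.

The skin conductance response function (SCRF) is defined implicitly by the
third-order constant-coefficient linear ODE

    x''' + th1 x'' + th2 x' + th3 x + g * u(t - th4) = 0,

with zero initial conditions.  As printed, a positive input drives ``x``
negative; the gain ``g`` is unconstrained in sign and absorbs polarity, so
fitted gains for positively recorded SCR are typically negative.  The input
delay ``th4`` acts on ``u`` via linear interpolation and may be negative (an
advance), as in fitted parameter sets where it compensates electrode-to-skin
conduction distance.

Numerical scheme
----------------
The solver is classical fixed-step RK4 on the data grid with 10× internal
substepping and linear interpolation of the input.  Because the system is
linear, one RK4 step is algebraically a linear recursion
``y[n+1] = T y[n] + Ba*u[n] + Bb*u[n+1]`` with constant matrices, which is
evaluated exactly through a discrete transfer function and
``scipy.signal.lfilter`` — bit-for-bit the RK4 trajectory (to rounding), at
vectorized speed.  Convergence is testable by halving the substep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidInputError, InvalidParameterError
from .timeseries import TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianBurstParams",
    "ScrfParams",
    "InputTrain",
    "gaussian_burst",
    "scrf_simulate",
    "scrf_impulse_response",
    "convolve_predict",
    "build_input_train",
]

#: default duration (s) of extracted impulse responses: covers the 25 s
#: post-event analysis window with margin.
DEFAULT_IR_DURATION = 30.0
#: pre-onset padding (s) used when extracting impulse responses, so that a
#: negative input delay (an advance) is representable.
IR_PRE_PAD = 5.0


@dataclass(frozen=True)
class GaussianBurstParams:
    """Parameters of the Gaussian sudomotor-burst model
    ``u(t) = A / (sqrt(2*pi)*sigma) * exp(-(t-mu)^2 / (2*sigma^2)) + c``.

    ``A`` is the burst area (amplitude × dispersion, in z-units·s), ``mu``
    the latency of the burst peak after the eliciting event (s), ``sigma``
    its dispersion (s), and ``c`` the baseline activity level.
    """

    A: float
    mu: float
    sigma: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        for name in ("A", "mu", "c"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    def peak_value(self) -> float:
        """Value at ``t = mu``."""
        return self.A / (np.sqrt(2 * np.pi) * self.sigma) + self.c

    def as_dict(self) -> dict:
        return {"A": self.A, "mu": self.mu, "sigma": self.sigma, "c": self.c}


@dataclass(frozen=True)
class ScrfParams:
    """Coefficients of the third-order ODE response function.

    ``theta1``–``theta3`` (units s⁻¹, s⁻², s⁻³) determine the shape of the
    response; ``theta4`` (s) is the input delay and has no transferable
    interpretation (it reflects electrode placement).
    """

    theta1: float
    theta2: float
    theta3: float
    theta4: float = 0.0

    def __post_init__(self) -> None:
        if self.theta3 == 0:
            raise InvalidParameterError("theta3 must be nonzero")
        for name in ("theta1", "theta2", "theta3", "theta4"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    def is_stable(self) -> bool:
        """Routh–Hurwitz criterion for the characteristic cubic
        ``s^3 + th1 s^2 + th2 s + th3``: all coefficients positive and
        ``th1*th2 > th3``."""
        return (
            self.theta1 > 0
            and self.theta2 > 0
            and self.theta3 > 0
            and self.theta1 * self.theta2 > self.theta3
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.theta1, self.theta2, self.theta3, self.theta4)

    def as_dict(self) -> dict:
        return {
            "theta1": self.theta1,
            "theta2": self.theta2,
            "theta3": self.theta3,
            "theta4": self.theta4,
        }


@dataclass(frozen=True)
class InputTrain:
    """A stimulation train modelled as a sum of Gaussian bursts.

    Each onset contributes a Gaussian of standard deviation ``sigma_in``
    (default 0.3 s, the dispersion of recorded sudomotor bursts) and area
    equal to its amplitude (unit area by default), so that the response gain
    keeps a consistent meaning across ``sigma_in`` choices.
    """

    onsets: tuple
    sigma_in: float = 0.3
    amplitudes: tuple | None = None

    def __post_init__(self) -> None:
        if not self.sigma_in > 0:
            raise InvalidParameterError("sigma_in must be > 0")
        onsets = np.asarray(self.onsets, dtype=float)
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            raise InvalidParameterError("onsets must be strictly increasing")
        object.__setattr__(self, "onsets", tuple(onsets))
        if self.amplitudes is not None:
            amps = tuple(float(a) for a in self.amplitudes)
            if len(amps) != len(onsets):
                raise InvalidParameterError("amplitudes must match onsets")
            object.__setattr__(self, "amplitudes", amps)


def gaussian_burst(t_grid: np.ndarray, p: GaussianBurstParams) -> TimeSeries:
    """Evaluate the Gaussian burst model on a uniform time grid."""
    t = np.asarray(t_grid, dtype=float)
    if t.size < 2:
        raise InvalidInputError("t_grid needs at least 2 points")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise InvalidInputError("t_grid must be uniform")
    u = p.A / (np.sqrt(2 * np.pi) * p.sigma) * np.exp(
        -((t - p.mu) ** 2) / (2 * p.sigma**2)
    ) + p.c
    return TimeSeries(u, rate=1.0 / dt[0], start=float(t[0]), channel="sn_model")


def _rk4_transfer(theta: ScrfParams, gain: float, h: float):
    """Discrete transfer function (num, den) of one exact RK4 step of the
    ODE with linearly interpolated input, at internal step ``h``."""
    th1, th2, th3, _ = theta.as_tuple()
    A = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [-th3, -th2, -th1]])
    E = np.array([0.0, 0.0, -gain])
    I3 = np.eye(3)
    A2 = A @ A
    A3 = A2 @ A
    A4 = A3 @ A
    T = I3 + h * A + h**2 / 2 * A2 + h**3 / 6 * A3 + h**4 / 24 * A4
    # input-weight vectors of the RK4 update, for u[n], the midpoint, u[n+1]
    W0 = h / 6 * (I3 + h * A + h**2 / 2 * A2 + h**3 / 4 * A3) @ E
    Wm = h / 6 * (4 * I3 + 2 * h * A + h**2 / 2 * A2) @ E
    W1 = h / 6 * E
    # midpoint by linear interpolation: u_mid = (u[n] + u[n+1]) / 2
    Ba = W0 + Wm / 2
    Bb = W1 + Wm / 2
    C = np.array([[1.0, 0.0, 0.0]])
    D = [[0.0]]
    num_a, den = sps.ss2tf(T, Ba[:, None], C, D)
    num_b, _ = sps.ss2tf(T, Bb[:, None], C, D)
    # y[n+1] = T y[n] + Ba u[n] + Bb u[n+1]; the Bb path sees the input
    # advanced by one sample, i.e. its transfer numerator is multiplied by z.
    num = np.zeros(4)
    num[1:] += num_a[0][-3:]
    num[:3] += num_b[0][-3:]
    return num, den


def scrf_simulate(
    theta: ScrfParams,
    u: TimeSeries,
    gain: float = 1.0,
    substeps: int = 10,
) -> TimeSeries:
    """Simulate the ODE response to input ``u`` from zero initial conditions.

    The input is delayed by ``theta4`` with linear interpolation; outside
    the recorded grid it is held at its edge values.  Unstable parameter
    sets are simulated anyway, with a logged warning.
    """
    if substeps < 1:
        raise InvalidParameterError("substeps must be >= 1")
    if not theta.is_stable():
        logger.warning("simulating unstable parameter set %s", theta.as_tuple())
    n = len(u)
    h = u.dt / substeps
    t_data = np.arange(n) * u.dt
    t_fine = np.arange((n - 1) * substeps + 1) * h
    u_fine = np.interp(t_fine - theta.theta4, t_data, u.values)
    num, den = _rk4_transfer(theta, gain, h)
    x_fine = sps.lfilter(num, den, u_fine)
    x = x_fine[::substeps]
    return u.copy_with(values=x, channel="scr_model")


def scrf_impulse_response(
    theta: ScrfParams,
    dt: float = 0.1,
    duration: float = DEFAULT_IR_DURATION,
    input_kind: str = "delta",
    sigma_in: float = 0.3,
    gain: float = 1.0,
    pre_pad: float = IR_PRE_PAD,
) -> TimeSeries:
    """Response to a unit-area input of the chosen kind.

    ``input_kind`` is ``"delta"`` (a one-sample discrete impulse of area 1)
    or ``"gaussian"`` (a unit-area Gaussian of dispersion ``sigma_in``).
    The returned series starts at ``-pre_pad`` seconds relative to the input
    onset, so that responses advanced by a negative ``theta4`` are captured
    rather than truncated.
    """
    if dt <= 0 or duration <= 0 or pre_pad < 0:
        raise InvalidParameterError("dt, duration must be > 0 and pre_pad >= 0")
    n = int(round((duration + pre_pad) / dt)) + 1
    t = np.arange(n) * dt - pre_pad
    if input_kind == "delta":
        u = np.zeros(n)
        k0 = int(round(pre_pad / dt))
        u[k0] = 1.0 / dt
    elif input_kind == "gaussian":
        u = np.exp(-(t**2) / (2 * sigma_in**2)) / (np.sqrt(2 * np.pi) * sigma_in)
    else:
        raise InvalidParameterError(f"unknown input_kind {input_kind!r}")
    series = TimeSeries(u, rate=1.0 / dt, start=-pre_pad, channel="ir_input")
    out = scrf_simulate(theta, series, gain=gain)
    return out.copy_with(channel="scrf_ir")


def convolve_predict(ir: TimeSeries, sn: TimeSeries, gain: float = 1.0) -> TimeSeries:
    """Predict the response to input ``sn`` by discrete convolution with the
    impulse response ``ir``, scaled by ``gain`` and the sample interval.

    ``ir.start`` may be negative (see :func:`scrf_impulse_response`); the
    output is aligned to ``sn``'s grid and truncated to its length.
    """
    if abs(ir.rate - sn.rate) > 1e-9 * sn.rate:
        raise InvalidParameterError(
            f"rate mismatch: ir {ir.rate} vs input {sn.rate} samples/s"
        )
    full = np.convolve(sn.values, ir.values) * gain * sn.dt
    k_off = int(round(-ir.start * ir.rate))
    out = np.zeros(len(sn))
    src = full[k_off : k_off + len(sn)]
    out[: len(src)] = src
    return sn.copy_with(values=out, channel="scr_pred")


def build_input_train(
    train: InputTrain, rate: float, duration: float
) -> TimeSeries:
    """Render a stimulation train as a sum of unit-area Gaussians at
    ``rate`` over ``[0, duration)``; each Gaussian's area equals its
    amplitude."""
    if not rate > 0 or not duration > 0:
        raise InvalidParameterError("rate and duration must be > 0")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    u = np.zeros(n)
    amps = train.amplitudes or (1.0,) * len(train.onsets)
    s = train.sigma_in
    norm = 1.0 / (np.sqrt(2 * np.pi) * s)
    for onset, amp in zip(train.onsets, amps):
        if not 0 <= onset < duration:
            raise InvalidParameterError(
                f"onset {onset} outside [0, {duration}) s"
            )
        # evaluate only within +-6 sigma for speed on long dense trains
        i0 = max(0, int((onset - 6 * s) * rate))
        i1 = min(n, int((onset + 6 * s) * rate) + 1)
        u[i0:i1] += amp * norm * np.exp(-((t[i0:i1] - onset) ** 2) / (2 * s**2))
    return TimeSeries(u, rate=rate, channel="input_train")
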