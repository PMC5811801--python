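"""Synthetic electrodermal datasets with known ground truth.

Two dataset styles mirror the two invasive experimental designs the
analysis targets:

- ``exp1`` (intraneural recording): sparse sensory events (>= 30 s apart)
  elicit Gaussian sudomotor bursts in an integrated nerve channel and,
  through the ODE response function, skin conductance responses; both
  channels are emitted at 10 Hz with additive broadband noise and slow
  sinusoidal drift.
- ``exp2`` (intraneural stimulation): near-periodic stimulation trains at
  several rates drive the response function; the conductance signal is
  recorded through an emulated first-derivative recording device
  (AC-coupled amplifier with a 0.3 s rise and 3 s decay time constant) at
  100 Hz.

A multiplicative gain-depletion state variable emulates the empirically
observed breakdown of time invariance at stimulation rates above ~0.6 Hz:
each burst transiently depletes the effective response gain, which recovers
with a 20 s time constant — negligible below 0.2 Hz, strong above 1 Hz.

Everything is a pure function of (config, seed); regeneration is
bit-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import InvalidParameterError
from .lti import (
    GaussianBurstParams,
    InputTrain,
    ScrfParams,
    build_input_train,
    convolve_predict,
    scrf_impulse_response,
)
from .signal_prep import butter_filter
from .timeseries import EventSchedule, TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "make_schedule",
    "synth_sn",
    "synth_scr",
    "apply_depletion",
    "emulate_derivative_recorder",
    "synth_raw_nerve",
    "generate_dataset",
]

#: Gaussian burst defaults: latency ~1.7 s, dispersion ~0.3 s, as estimated
#: from recorded sudomotor bursts evoked by aversive sounds.
DEFAULT_BURST = GaussianBurstParams(A=0.7814, mu=1.6850, sigma=0.3051, c=0.1567)
#: response-function defaults: the low-stimulation-rate parameter set.
DEFAULT_THETA = ScrfParams(2.3051, 2.5653, 0.1517, -0.0058)


@dataclass
class SyntheticConfig:
    """Study-design and ground-truth parameters for dataset generation.

    Noise and drift amplitudes are fractions of the noiseless signal's
    standard deviation.  Gains are drawn log-normally around ``gain_mean``
    (between-epoch SD ``gain_sd`` on the log scale) with an optional
    additive linear repetition trend.
    """

    # population
    n_subjects: int = 7
    # exp1 design: events per type, minimum inter-event gap with jitter
    events_per_type: dict = field(default_factory=lambda: {"aversive": 20, "oddball": 10})
    min_gap: float = 30.0
    gap_jitter: float = 5.0
    lead_in: float = 30.0
    # exp2 design: one epoch per rate per subject
    stimulation_rates: tuple = (0.1, 0.2, 0.5, 1.5)
    epoch_duration: float = 120.0
    epoch_gap: float = 30.0
    include_excluded_rate: bool = True   # adds a short ~10 Hz epoch
    excluded_rate: float = 10.0
    excluded_epoch_duration: float = 20.0
    rate_jitter: float = 0.05            # fractional onset jitter, exp2
    # ground truth
    burst: GaussianBurstParams = field(default_factory=lambda: DEFAULT_BURST)
    theta: ScrfParams = field(default_factory=lambda: DEFAULT_THETA)
    theta_by_subject: dict | None = None
    sigma_in: float = 0.3
    # gain model
    gain_mean: float = 1.0
    gain_sd: float = 0.3
    gain_trend: float = 0.0
    # noise and drift
    noise_sd: float = 0.05
    drift_amplitude: float = 0.1
    drift_freq: float = 0.005
    # depletion nonlinearity
    depletion_enabled: bool = True
    depletion_delta: float = 0.3
    depletion_tau_rec: float = 20.0
    # rates
    rate: float = 10.0        # analysis rate (exp1 channels)
    raw_rate: float = 100.0   # exp2 recorder rate
    # derivative recorder
    recorder_rise: float = 0.3
    recorder_decay: float = 3.0
    recorder_extra_highpass_hz: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidParameterError("need at least one subject")
        for name in ("gain_sd", "noise_sd", "drift_amplitude"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0 <= self.depletion_delta < 1:
            raise InvalidParameterError("depletion_delta must be in [0, 1)")
        if self.depletion_tau_rec <= 0:
            raise InvalidParameterError("depletion_tau_rec must be > 0")
        if any(r <= 0 for r in self.stimulation_rates):
            raise InvalidParameterError("stimulation rates must be > 0")

    def theta_for(self, subject: str) -> ScrfParams:
        if self.theta_by_subject and subject in self.theta_by_subject:
            return self.theta_by_subject[subject]
        return self.theta

    def as_dict(self) -> dict:
        d = asdict(self)
        d["burst"] = self.burst.as_dict()
        d["theta"] = self.theta.as_dict()
        if self.theta_by_subject:
            d["theta_by_subject"] = {
                k: v.as_dict() for k, v in self.theta_by_subject.items()
            }
        return d


def make_schedule(
    cfg: SyntheticConfig,
    style: str = "exp1",
    subject: str = "s01",
    rng: np.random.Generator | None = None,
) -> EventSchedule:
    """Event onsets for one subject.

    ``exp1``: per event type, onsets separated by at least ``min_gap``
    seconds plus exponential jitter (the design constraint that lets SCR
    tails resolve).  ``exp2``: near-periodic onsets at each epoch's
    stimulation rate with at most ``rate_jitter`` fractional jitter; epoch
    membership is encoded in the event type (``"epoch00"``, ...).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if style == "exp1":
        onsets: list[float] = []
        types: list[str] = []
        t = cfg.lead_in
        for etype, n in cfg.events_per_type.items():
            for _ in range(n):
                onsets.append(t)
                types.append(etype)
                t += cfg.min_gap + float(rng.exponential(cfg.gap_jitter))
        return EventSchedule(np.array(onsets), types, subject=subject)
    if style == "exp2":
        onsets = []
        types = []
        reps: list[int] = []
        t0 = cfg.lead_in
        epoch_specs = list(cfg.stimulation_rates)
        durations = [cfg.epoch_duration] * len(epoch_specs)
        if cfg.include_excluded_rate:
            epoch_specs.append(cfg.excluded_rate)
            durations.append(cfg.excluded_epoch_duration)
        for j, (r, dur) in enumerate(zip(epoch_specs, durations)):
            period = 1.0 / r
            n_ev = int(np.floor(dur / period))
            if n_ev < 2:
                raise InvalidParameterError(
                    f"epoch at {r} Hz / {dur} s holds fewer than 2 events"
                )
            base = t0 + period / 2 + period * np.arange(n_ev)
            jit = rng.uniform(-cfg.rate_jitter, cfg.rate_jitter, n_ev) * period
            ons = np.sort(base + jit)
            onsets.extend(ons.tolist())
            types.extend([f"epoch{j:02d}"] * n_ev)
            reps.extend(range(1, n_ev + 1))
            t0 += dur + cfg.epoch_gap
        return EventSchedule(np.array(onsets), types, np.array(reps), subject=subject)
    raise InvalidParameterError(f"unknown style {style!r}")


def synth_sn(
    schedule: EventSchedule,
    burst: GaussianBurstParams,
    noise_sd: float,
    rate: float,
    duration: float,
    rng: np.random.Generator | None = None,
    drift_amplitude: float = 0.0,
    drift_freq: float = 0.005,
) -> TimeSeries:
    """Integrated sudomotor-nerve channel: baseline + one Gaussian burst per
    event (peaking ``mu`` seconds after onset) + white noise + optional slow
    sinusoidal drift.  ``noise_sd`` and ``drift_amplitude`` are absolute
    (signal units) here; :func:`generate_dataset` converts fractions."""
    rng = rng or np.random.default_rng(0)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    u = np.full(n, burst.c)
    norm = burst.A / (np.sqrt(2 * np.pi) * burst.sigma)
    for onset in schedule.onsets:
        center = onset + burst.mu
        i0 = max(0, int((center - 6 * burst.sigma) * rate))
        i1 = min(n, int((center + 6 * burst.sigma) * rate) + 1)
        u[i0:i1] += norm * np.exp(-((t[i0:i1] - center) ** 2) / (2 * burst.sigma**2))
    if drift_amplitude:
        u += drift_amplitude * np.sin(2 * np.pi * drift_freq * t)
    if noise_sd:
        u += rng.normal(0.0, noise_sd, n)
    return TimeSeries(u, rate=rate, units="z", channel="sn")


def synth_scr(
    onsets: np.ndarray,
    gains: np.ndarray,
    theta: ScrfParams,
    rate: float,
    duration: float,
    sigma_in: float = 0.3,
    noise_sd: float = 0.0,
    drift_amplitude: float = 0.0,
    drift_freq: float = 0.005,
    rng: np.random.Generator | None = None,
) -> TimeSeries:
    """Skin conductance from a gain-weighted burst train through the ODE.

    Each onset contributes a unit-area Gaussian burst scaled by its gain;
    the response is rendered by convolution with the response function's
    impulse response at sign flipped to the conventional positive-going SCR
    polarity (the ODE as written drives the state negative).  ``noise_sd``
    and ``drift_amplitude`` are absolute here.
    """
    rng = rng or np.random.default_rng(0)
    train = build_input_train(
        InputTrain(tuple(onsets), sigma_in=sigma_in, amplitudes=tuple(gains)),
        rate=rate,
        duration=duration,
    )
    ir = scrf_impulse_response(theta, dt=1.0 / rate, duration=60.0)
    scr = convolve_predict(ir, train, gain=-1.0)
    x = scr.values
    if drift_amplitude:
        t = np.arange(len(x)) / rate
        x = x + drift_amplitude * np.sin(2 * np.pi * drift_freq * t)
    if noise_sd:
        x = x + rng.normal(0.0, noise_sd, len(x))
    return TimeSeries(x, rate=rate, units="uS", channel="scr")


def apply_depletion(
    gains: np.ndarray,
    onsets: np.ndarray,
    delta: float,
    tau_rec: float,
) -> np.ndarray:
    """Multiplicative gain depletion with exponential recovery.

    A state ``s`` starts at 1; at each onset the effective gain is
    ``g * s`` (state *before* the burst), then ``s <- s * (1 - delta)``;
    between onsets ``s`` relaxes toward 1 as
    ``s(t) = 1 - (1 - s) * exp(-dt / tau_rec)``.
    """
    if not 0 <= delta < 1:
        raise InvalidParameterError("delta must be in [0, 1)")
    if tau_rec <= 0:
        raise InvalidParameterError("tau_rec must be > 0")
    gains = np.asarray(gains, float)
    onsets = np.asarray(onsets, float)
    out = np.empty_like(gains)
    s = 1.0
    t_prev = None
    for k, t in enumerate(onsets):
        if t_prev is not None:
            s = 1.0 - (1.0 - s) * np.exp(-(t - t_prev) / tau_rec)
        out[k] = gains[k] * s
        s *= 1.0 - delta
        t_prev = t
    return out


def emulate_derivative_recorder(
    scr: TimeSeries,
    rise: float = 0.3,
    decay: float = 3.0,
    extra_highpass_hz: float | None = None,
    explicit_diff: bool = False,
) -> TimeSeries:
    """First-derivative recording device (AC-coupled galvanic amplifier).

    The device's decay time constant acts as a first-order high-pass
    (cutoff ``1/(2*pi*decay)`` Hz), which for signals slower than ``decay``
    *is* a scaled differentiation; the rise time constant is a first-order
    low-pass (cutoff ``1/(2*pi*rise)`` Hz).  With ``explicit_diff=True``
    a literal first difference is taken before the shaping filters instead,
    which double-differentiates slow signals.  ``extra_highpass_hz`` adds
    one more first-order high-pass stage (off by default: applied within
    the conductance band it would remove essentially all response energy,
    which is incompatible with the information the reconstructed signal
    demonstrably carries).
    """
    if scr.rate < 10:
        raise InvalidParameterError("recorder emulation needs >= 10 samples/s")
    out = scr
    if explicit_diff:
        d = np.diff(out.values, prepend=out.values[0])
        out = out.copy_with(values=d)
        out = butter_filter(out, high_cut=1.0 / (2 * np.pi * rise), order=1)
        out = butter_filter(out, low_cut=1.0 / (2 * np.pi * decay), order=1)
    else:
        out = butter_filter(out, low_cut=1.0 / (2 * np.pi * decay), order=1)
        out = butter_filter(out, high_cut=1.0 / (2 * np.pi * rise), order=1)
    if extra_highpass_hz:
        out = butter_filter(out, low_cut=extra_highpass_hz, order=1)
    return out.copy_with(units="uS/s", channel="scr_deriv")


def synth_raw_nerve(
    schedule: EventSchedule,
    burst: GaussianBurstParams,
    rate: float = 10000.0,
    duration: float = 10.0,
    background_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> TimeSeries:
    """Raw high-rate microneurography emulation for exercising the FIR
    band-pass and the rectified leaky integrator: broadband noise whose
    envelope is the Gaussian burst profile, over a noise floor.  Generated
    only on demand (high memory cost at 10 kHz)."""
    rng = rng or np.random.default_rng(0)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    envelope = np.full(n, max(burst.c, 0.0))
    norm = burst.A / (np.sqrt(2 * np.pi) * burst.sigma)
    for onset in schedule.onsets:
        center = onset + burst.mu
        envelope += norm * np.exp(-((t - center) ** 2) / (2 * burst.sigma**2))
    x = rng.normal(0.0, 1.0, n) * (background_sd + envelope)
    return TimeSeries(x, rate=rate, units="uV", channel="sn_raw")


@dataclass
class SyntheticDataset:
    """Signals, schedules and ground truth of one generated dataset."""

    style: str
    signals: dict            # subject -> {channel: TimeSeries}
    schedules: dict          # subject -> EventSchedule
    truth: dict              # ground-truth record (params, gains, epochs)
    config: SyntheticConfig
    seed: int

    @property
    def subjects(self) -> list[str]:
        return sorted(self.signals)

    def content_hash(self) -> str:
        """Deterministic digest over all signals and schedules."""
        h = hashlib.sha256()
        for subj in self.subjects:
            for ch in sorted(self.signals[subj]):
                ts = self.signals[subj][ch]
                h.update(ch.encode())
                h.update(np.round(ts.values, 12).tobytes())
            sched = self.schedules[subj]
            h.update(np.round(sched.onsets, 9).tobytes())
            h.update(",".join(sched.types).encode())
        return h.hexdigest()


def _subject_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _gain_draw(
    cfg: SyntheticConfig, repetition: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    g = cfg.gain_mean * np.exp(rng.normal(0.0, cfg.gain_sd, len(repetition)))
    if cfg.gain_trend:
        g = g + cfg.gain_trend * (np.asarray(repetition, float) - 1.0)
    return g


def generate_dataset(cfg: SyntheticConfig, style: str = "exp1") -> SyntheticDataset:
    """Generate a full multi-subject dataset of the requested style.

    ``exp1`` emits per subject a 10 Hz integrated nerve channel (``sn``)
    and a 10 Hz conductance channel (``scr``).  ``exp2`` emits per subject
    a 100 Hz derivative-recorder channel (``scr_deriv``) together with the
    underlying noiseless conductance (``scr_true``, for validation only).
    The truth record carries everything needed to regenerate and verify:
    per-subject response functions, per-event gains before and after
    depletion, noise levels and epoch layout.
    """
    if style not in ("exp1", "exp2"):
        raise InvalidParameterError(f"unknown style {style!r}")
    rngs = _subject_rngs(cfg.seed, 3 * cfg.n_subjects)
    signals: dict = {}
    schedules: dict = {}
    truth: dict = {
        "style": style,
        "seed": cfg.seed,
        "burst": cfg.burst.as_dict(),
        "subjects": {},
    }
    for i in range(cfg.n_subjects):
        subject = f"s{i + 1:02d}"
        rng_sched, rng_gain, rng_noise = rngs[3 * i : 3 * i + 3]
        theta = cfg.theta_for(subject)
        sched = make_schedule(cfg, style=style, subject=subject, rng=rng_sched)
        schedules[subject] = sched
        rec: dict = {"theta": theta.as_dict()}
        if style == "exp1":
            duration = float(sched.onsets[-1] + 40.0)
            gains = _gain_draw(cfg, sched.repetition, rng_gain)
            eff = gains
            if cfg.depletion_enabled:
                eff = apply_depletion(
                    gains, sched.onsets, cfg.depletion_delta, cfg.depletion_tau_rec
                )
            # nerve channel (includes burst baseline, noise scaled to the
            # noiseless burst signal's SD)
            clean_sn = synth_sn(sched, cfg.burst, 0.0, cfg.rate, duration)
            sn_scale = float(np.std(clean_sn.values - cfg.burst.c)) or 1.0
            sn = synth_sn(
                sched, cfg.burst, cfg.noise_sd * sn_scale, cfg.rate, duration,
                rng=rng_noise,
                drift_amplitude=cfg.drift_amplitude * sn_scale,
                drift_freq=cfg.drift_freq,
            )
            # conductance channel: burst area A per event, times gain
            centers = sched.onsets + cfg.burst.mu
            amps = eff * cfg.burst.A
            clean = synth_scr(
                centers, amps, theta, cfg.rate, duration, sigma_in=cfg.burst.sigma
            )
            scale = float(np.std(clean.values)) or 1.0
            scr_vals = clean.values.copy()
            t = np.arange(len(scr_vals)) / cfg.rate
            if cfg.drift_amplitude:
                scr_vals += cfg.drift_amplitude * scale * np.sin(
                    2 * np.pi * cfg.drift_freq * t
                )
            if cfg.noise_sd:
                scr_vals += rng_noise.normal(0.0, cfg.noise_sd * scale, len(scr_vals))
            signals[subject] = {
                "sn": sn,
                "scr": TimeSeries(scr_vals, rate=cfg.rate, units="uS", channel="scr"),
            }
            rec.update(
                {
                    "gains": gains.tolist(),
                    "effective_gains": eff.tolist(),
                    "noise_sd_abs": cfg.noise_sd * scale,
                    "duration": duration,
                }
            )
        else:  # exp2
            duration = float(sched.onsets[-1] + 40.0)
            gains = _gain_draw(cfg, sched.repetition, rng_gain)
            eff = gains
            if cfg.depletion_enabled:
                eff = apply_depletion(
                    gains, sched.onsets, cfg.depletion_delta, cfg.depletion_tau_rec
                )
            clean = synth_scr(
                sched.onsets, eff, theta, cfg.raw_rate, duration,
                sigma_in=cfg.sigma_in,
            )
            scale = float(np.std(clean.values)) or 1.0
            scr_vals = clean.values.copy()
            t = np.arange(len(scr_vals)) / cfg.raw_rate
            if cfg.drift_amplitude:
                scr_vals += cfg.drift_amplitude * scale * np.sin(
                    2 * np.pi * cfg.drift_freq * t
                )
            if cfg.noise_sd:
                scr_vals += rng_noise.normal(0.0, cfg.noise_sd * scale, len(scr_vals))
            scr = TimeSeries(scr_vals, rate=cfg.raw_rate, units="uS", channel="scr")
            deriv = emulate_derivative_recorder(
                scr,
                rise=cfg.recorder_rise,
                decay=cfg.recorder_decay,
                extra_highpass_hz=cfg.recorder_extra_highpass_hz,
            )
            signals[subject] = {"scr_deriv": deriv, "scr_true": clean}
            # epoch layout from the schedule's epoch-coded types
            epochs = []
            for etype in sorted(set(sched.types)):
                idx = [k for k, t_ in enumerate(sched.types) if t_ == etype]
                ons = sched.onsets[idx]
                epochs.append(
                    {
                        "label": etype,
                        "event_indices": idx,
                        "start": float(ons[0]),
                        "end": float(ons[-1]),
                        "n_events": len(idx),
                        "mean_rate": float((len(idx) - 1) / (ons[-1] - ons[0]))
                        if len(idx) > 1
                        else float("nan"),
                    }
                )
            rec.update(
                {
                    "gains": gains.tolist(),
                    "effective_gains": eff.tolist(),
                    "noise_sd_abs": cfg.noise_sd * scale,
                    "duration": duration,
                    "epochs": epochs,
                }
            )
        truth["subjects"][subject] = rec
    return SyntheticDataset(
        style=style,
        signals=signals,
        schedules=schedules,
        truth=truth,
        config=cfg,
        seed=cfg.seed,
    )
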