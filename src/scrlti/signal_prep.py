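"""Deterministic preprocessing of skin-conductance and nerve recordings.

The standard chains are:

- skin conductance: 1st-order Butterworth high-pass (0.0159 Hz, i.e. a 10 s
  time constant) and low-pass (5 Hz) → z-score → decimate to 10 Hz;
- microneurographic nerve signal: order-398 equiripple FIR band-pass
  (300–4000 Hz) → z-score → full-wave rectified leaky integration
  (τ = 100 ms) → decimate to 10 Hz → piecewise linear detrend on 5 s windows;
- derivative-recorder channel (stimulation experiment): reconstruct the skin
  conductance by mean subtraction and cumulative summation, then treat as a
  skin-conductance channel.

All filters here are applied causally in a single pass.  Constant group
delays introduced this way are absorbed downstream by the latency parameters
of the burst model (µ) and of the response function (ϑ4), so no zero-phase
(forward–backward) filtering is used; users comparing against zero-phase
pipelines should expect a fixed latency offset, not a shape difference.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal as sps

from .exceptions import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
)
from .timeseries import Epoch, EventSchedule, TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "butter_filter",
    "fir_bandpass_nerve",
    "zscore",
    "rectified_leaky_integrate",
    "downsample",
    "piecewise_detrend",
    "reconstruct_scr_from_derivative",
    "extract_epochs",
    "minimum_correct",
    "average_epochs",
    "detect_clipping",
    "preprocess_scr",
    "preprocess_integrated_nerve",
]


def butter_filter(
    ts: TimeSeries,
    low_cut: float | None = None,
    high_cut: float | None = None,
    order: int = 1,
) -> TimeSeries:
    """Causal Butterworth filtering (single pass, bilinear discretization).

    ``low_cut`` is a high-pass cutoff (frequencies *below* it are removed)
    and ``high_cut`` a low-pass cutoff; giving both yields a band-pass built
    as a cascade of a 1st-order-per-section high- and low-pass, matching the
    "first-order band-pass" terminology of electrodermal preprocessing.

    A ``high_cut`` exactly at the Nyquist frequency is treated as a no-op
    (the filter would be the identity there anyway).
    """
    if low_cut is None and high_cut is None:
        raise InvalidParameterError("at least one of low_cut/high_cut is required")
    if len(ts) < 2:
        raise InvalidInputError("cannot filter a series of fewer than 2 samples")
    nyq = ts.rate / 2.0
    x = ts.values
    if low_cut is not None:
        if not 0 < low_cut < nyq:
            raise InvalidParameterError(
                f"high-pass cutoff {low_cut} Hz outside (0, {nyq}) Hz"
            )
        b, a = sps.butter(order, low_cut / nyq, btype="highpass")
        x = sps.lfilter(b, a, x)
    if high_cut is not None:
        if high_cut == nyq:
            logger.debug("low-pass cutoff at Nyquist, skipping (identity)")
        elif not 0 < high_cut < nyq:
            raise InvalidParameterError(
                f"low-pass cutoff {high_cut} Hz outside (0, {nyq}) Hz"
            )
        else:
            b, a = sps.butter(order, high_cut / nyq, btype="lowpass")
            x = sps.lfilter(b, a, x)
    logger.debug(
        "butter_filter low_cut=%s high_cut=%s order=%d: out sd=%.4g",
        low_cut, high_cut, order, float(np.std(x)),
    )
    return ts.copy_with(values=x)


# FIR design constants for the nerve band-pass: order 398 (399 taps),
# pass band 300-4000 Hz with 50 Hz transition bands.
_FIR_ORDER = 398
_FIR_BAND = (300.0, 4000.0)
_FIR_TRANSITION = 50.0


def fir_bandpass_nerve(ts: TimeSeries) -> TimeSeries:
    """Order-398 equiripple (Parks–McClellan) FIR band-pass, 300–4000 Hz.

    The linear-phase group delay (199 samples) is compensated by shifting
    the output left and edge-padding, so burst latencies are unbiased.
    """
    lo, hi = _FIR_BAND
    if ts.rate < 2 * (hi + _FIR_TRANSITION):
        raise InvalidParameterError(
            f"sampling rate {ts.rate} too low for a {hi} Hz pass-band edge"
        )
    numtaps = _FIR_ORDER + 1
    bands = [0, lo - _FIR_TRANSITION, lo, hi, hi + _FIR_TRANSITION, ts.rate / 2]
    taps = sps.remez(numtaps, bands, [0, 1, 0], fs=ts.rate)
    delay = _FIR_ORDER // 2
    padded = np.concatenate([ts.values, np.full(delay, ts.values[-1])])
    y = sps.lfilter(taps, [1.0], padded)[delay:]
    return ts.copy_with(values=y)


def zscore(ts: TimeSeries) -> TimeSeries:
    """Standardize to zero mean and unit sample standard deviation (ddof=0)."""
    if len(ts) < 2:
        raise InvalidInputError("z-scoring needs at least 2 samples")
    sd = float(np.std(ts.values))
    if sd == 0.0:
        raise DegenerateInputError("cannot z-score a constant series")
    z = (ts.values - np.mean(ts.values)) / sd
    return ts.copy_with(values=z, units="z")


def rectified_leaky_integrate(ts: TimeSeries, tau: float = 0.1) -> TimeSeries:
    """Full-wave rectification followed by a leaky integrator.

    Recurrence: ``y[n] = a*y[n-1] + (1-a)*|x[n]|`` with ``a = exp(-dt/tau)``
    and ``y[0] = (1-a)*|x[0]|``.  The ``(1-a)`` input weight makes the
    integrator unit-gain for a constant envelope.  Rectification is applied
    because the integrated envelope of a zero-mean multi-unit nerve signal
    would otherwise vanish.
    """
    if not tau > 0:
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    alpha = float(np.exp(-ts.dt / tau))
    y = sps.lfilter([1.0 - alpha], [1.0, -alpha], np.abs(ts.values))
    return ts.copy_with(values=y)


def downsample(ts: TimeSeries, target_rate: float) -> TimeSeries:
    """Decimate by an integer factor, keeping the first sample of each block.

    The caller is responsible for having low-pass filtered the signal below
    the target Nyquist frequency beforehand (no anti-alias filter is applied
    here, mirroring a plain decimation step).
    """
    if not target_rate > 0:
        raise InvalidParameterError("target_rate must be > 0")
    factor = ts.rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise InvalidParameterError(
            f"rate {ts.rate} is not an integer multiple of target {target_rate}"
        )
    factor = int(round(factor))
    return ts.copy_with(values=ts.values[::factor].copy(), rate=target_rate)


def piecewise_detrend(ts: TimeSeries, window: float = 5.0) -> TimeSeries:
    """Remove an OLS line within each consecutive ``window``-second block.

    A final partial block is detrended likewise if it has at least 2
    samples, else passed through unchanged.
    """
    w = int(round(window * ts.rate))
    if w < 2:
        raise InvalidParameterError("detrend window must span at least 2 samples")
    x = ts.values.copy()
    n = len(x)
    for i0 in range(0, n, w):
        block = x[i0 : i0 + w]
        if block.size < 2:
            continue
        t = np.arange(block.size, dtype=float)
        slope, intercept = np.polyfit(t, block, 1)
        block -= slope * t + intercept
    return ts.copy_with(values=x)


def reconstruct_scr_from_derivative(ts: TimeSeries) -> TimeSeries:
    """Integrate a first-derivative recording back into a conductance signal.

    Implements the mean-subtract-and-cumulative-sum rule:
    ``out[n] = sum_{k<=n} (x[k] - mean(x))``; the last output sample is 0 up
    to rounding.  The result is in arbitrary (integrated) units; slow drift
    introduced by the integration is expected to be removed by the
    subsequent high-pass filtering.
    """
    if len(ts) < 2:
        raise InvalidInputError("reconstruction needs at least 2 samples")
    y = np.cumsum(ts.values - np.mean(ts.values))
    return ts.copy_with(values=y, channel="scr_reconstructed")


def extract_epochs(
    ts: TimeSeries,
    events: EventSchedule,
    pre: float = 5.0,
    post: float = 25.0,
) -> list[Epoch]:
    """Cut one half-open window ``[onset-pre, onset+post)`` per event.

    Events whose window falls outside the recording are skipped with a
    logged warning (they appear in no output epoch).
    """
    n_window = int(round((pre + post) * ts.rate))
    epochs: list[Epoch] = []
    for i, onset in enumerate(events.onsets):
        i0 = int(round((onset - pre - ts.start) * ts.rate))
        if i0 < 0 or i0 + n_window > len(ts):
            warnings.warn(
                f"event {i} at {onset:.2f} s: window outside recording, skipped",
                stacklevel=2,
            )
            logger.warning("extract_epochs: skipping out-of-bounds event %d", i)
            continue
        epochs.append(
            Epoch(
                values=ts.values[i0 : i0 + n_window].copy(),
                rate=ts.rate,
                pre=pre,
                post=post,
                event_type=events.types[i],
                subject=events.subject,
                index=i,
                repetition=int(events.repetition[i]),
                onset=float(onset),
            )
        )
    return epochs


def minimum_correct(epoch: Epoch) -> Epoch:
    """Subtract the epoch minimum, so the modelled response sits on a zero
    baseline representing conductance maintained without nerve firing."""
    values = epoch.values - epoch.values.min()
    out = Epoch(
        values=values,
        rate=epoch.rate,
        pre=epoch.pre,
        post=epoch.post,
        event_type=epoch.event_type,
        subject=epoch.subject,
        index=epoch.index,
        repetition=epoch.repetition,
        onset=epoch.onset,
        excluded=epoch.excluded,
        exclusion_reason=epoch.exclusion_reason,
        meta=dict(epoch.meta),
    )
    return out


def average_epochs(
    epochs: list[Epoch], by: str = "event_type"
) -> dict[tuple, Epoch]:
    """Pointwise mean of epochs per group.

    ``by`` is ``"event_type"`` (pool all subjects) or ``"subject_event_type"``
    (one average per subject × event type).  Excluded epochs are ignored;
    empty groups are omitted with a warning.  Keys are ``(event_type,)`` or
    ``(subject, event_type)`` tuples.
    """
    if by not in ("event_type", "subject_event_type"):
        raise InvalidParameterError(f"unknown grouping {by!r}")
    groups: dict[tuple, list[Epoch]] = {}
    for ep in epochs:
        if ep.excluded:
            continue
        key = (ep.event_type,) if by == "event_type" else (ep.subject, ep.event_type)
        groups.setdefault(key, []).append(ep)
    out: dict[tuple, Epoch] = {}
    for key, members in groups.items():
        if not members:
            warnings.warn(f"empty epoch group {key}, omitted", stacklevel=2)
            continue
        mean = np.mean([m.values for m in members], axis=0)
        proto = members[0]
        out[key] = Epoch(
            values=mean,
            rate=proto.rate,
            pre=proto.pre,
            post=proto.post,
            event_type=proto.event_type,
            subject=proto.subject if by == "subject_event_type" else "",
            index=-1,
            meta={"n_epochs": len(members)},
        )
    return out


def detect_clipping(
    ts: TimeSeries, level: float, min_run: int = 3
) -> list[tuple[int, int]]:
    """Flag maximal runs of >= ``min_run`` consecutive samples with
    ``|x| >= level``; returns half-open sample-index intervals."""
    if not level > 0:
        raise InvalidParameterError("clipping level must be > 0")
    mask = np.abs(ts.values) >= level
    intervals: list[tuple[int, int]] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        if i1 - i0 >= min_run:
            intervals.append((int(i0), int(i1)))
    return intervals


def preprocess_scr(
    ts: TimeSeries,
    low_cut: float = 0.0159,
    high_cut: float = 5.0,
    target_rate: float = 10.0,
) -> TimeSeries:
    """Standard skin-conductance chain: band-pass → z-score → decimate."""
    out = butter_filter(ts, low_cut=low_cut, high_cut=high_cut, order=1)
    out = zscore(out)
    if out.rate != target_rate:
        out = downsample(out, target_rate)
    return out


def preprocess_integrated_nerve(
    ts: TimeSeries,
    target_rate: float = 10.0,
    detrend_window: float = 5.0,
) -> TimeSeries:
    """Chain for an already integrated (envelope) nerve channel:
    z-score → decimate → piecewise detrend.

    For a raw high-rate microneurographic channel, run
    :func:`fir_bandpass_nerve`, :func:`zscore` and
    :func:`rectified_leaky_integrate` first.
    """
    out = zscore(ts)
    if out.rate != target_rate:
        out = downsample(out, target_rate)
    return piecewise_detrend(out, window=detrend_window)
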