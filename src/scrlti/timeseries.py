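"""Core containers: uniformly sampled time series, event schedules, epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = ["TimeSeries", "EventSchedule", "Epoch"]


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : array-like
        Sample values (signal units).
    rate : float
        Sampling rate in samples/s, must be > 0.
    start : float, optional
        Time of the first sample in seconds (default 0).
    units : str, optional
        Unit label, e.g. ``"uS"`` or ``"z"``.
    channel : str, optional
        Channel label, e.g. ``"scr"`` or ``"sn"``.
    """

    values: np.ndarray
    rate: float
    start: float = 0.0
    units: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise InvalidInputError("TimeSeries needs a 1-d, non-empty value array")
        if not self.rate > 0:
            raise InvalidParameterError(f"rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("TimeSeries values must all be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Span from first to last sample, in seconds."""
        return (len(self) - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(len(self)) / self.rate

    def copy_with(self, **changes) -> "TimeSeries":
        """Return a copy with selected fields replaced."""
        return replace(self, **changes)

    def slice_seconds(self, t0: float, t1: float) -> "TimeSeries":
        """Half-open slice [t0, t1) in absolute seconds."""
        i0 = int(round((t0 - self.start) * self.rate))
        i1 = int(round((t1 - self.start) * self.rate))
        if i0 < 0 or i1 > len(self) or i0 >= i1:
            raise InvalidInputError(
                f"slice [{t0}, {t1}) s outside recording "
                f"[{self.start}, {self.start + len(self) / self.rate}) s"
            )
        return self.copy_with(values=self.values[i0:i1].copy(), start=t0)


@dataclass
class EventSchedule:
    """Ordered event (or stimulation) onsets with per-event metadata.

    ``onsets`` are absolute seconds and must be strictly increasing;
    ``types`` and ``repetition`` carry one entry per onset.  ``repetition``
    is a 1-based event counter within its (subject, type) stream.
    """

    onsets: np.ndarray
    types: list[str]
    repetition: np.ndarray | None = None
    subject: str = ""

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1:
            raise InvalidInputError("onsets must be 1-d")
        if len(self.onsets) and np.any(np.diff(self.onsets) <= 0):
            raise InvalidInputError("onsets must be strictly increasing")
        self.types = list(self.types)
        if len(self.types) != len(self.onsets):
            raise InvalidInputError("types must match onsets in length")
        if self.repetition is None:
            # default: running count per event type
            counts: dict[str, int] = {}
            rep = []
            for t in self.types:
                counts[t] = counts.get(t, 0) + 1
                rep.append(counts[t])
            self.repetition = np.array(rep, dtype=int)
        else:
            self.repetition = np.asarray(self.repetition, dtype=int)
            if len(self.repetition) != len(self.onsets):
                raise InvalidInputError("repetition must match onsets in length")
            if len(self.repetition) and np.any(self.repetition < 1):
                raise InvalidInputError("repetition indices are 1-based positives")

    def __len__(self) -> int:
        return len(self.onsets)

    def shifted(self, offset_s: float) -> "EventSchedule":
        return EventSchedule(
            self.onsets + offset_s, self.types, self.repetition.copy(), self.subject
        )


@dataclass
class Epoch:
    """An event-locked data window at a fixed rate.

    The window is half-open, ``[onset - pre, onset + post)``; at the standard
    10 Hz analysis rate with pre=5 s and post=25 s this is 300 samples.
    """

    values: np.ndarray
    rate: float = 10.0
    pre: float = 5.0
    post: float = 25.0
    event_type: str = ""
    subject: str = ""
    index: int = 0
    repetition: int = 1
    onset: float = 0.0
    excluded: bool = False
    exclusion_reason: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_expected = int(round((self.pre + self.post) * self.rate))
        if self.values.size != n_expected:
            raise InvalidInputError(
                f"epoch has {self.values.size} samples, expected {n_expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("epoch values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Times relative to the event onset (negative during the pre window)."""
        return -self.pre + np.arange(len(self)) / self.rate
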