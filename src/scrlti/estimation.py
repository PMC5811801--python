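"""Inverse problems and variance analyses.

Functions here answer the quantitative questions of the LTI test: how much
of the conductance signal a response function explains, how the explained
variance decomposes across canonical / per-subject / per-epoch response
functions, how similar an estimated response function is to a reference
model, and whether the response gain drifts with event repetition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
)
from .lti import GaussianBurstParams, ScrfParams
from .models import GaussianBurstModel, GaussianBurstResults, ScrfModel, ScrfResults
from .timeseries import Epoch, TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "fit_gaussian_burst",
    "fit_scrf",
    "estimate_gain",
    "explained_variance",
    "variance_partition",
    "VariancePartition",
    "compare_scrf_to_reference",
    "ReferenceComparison",
    "gain_trend",
    "GainTrend",
    "classify_epochs_by_rate",
    "RATE_CLASS_THRESHOLDS",
]


def fit_gaussian_burst(
    epoch: Epoch, init: GaussianBurstParams | None = None, seed: int = 0
) -> GaussianBurstResults:
    """Fit the Gaussian burst model to a nerve epoch (see
    :class:`~scrlti.models.GaussianBurstModel`)."""
    return GaussianBurstModel.from_epoch(epoch).fit(start=init, seed=seed)


def fit_scrf(
    inp: TimeSeries,
    observed: TimeSeries,
    priors: dict | None = None,
    fit_gain: bool = True,
    seed: int = 0,
    start: ScrfParams | None = None,
    n_starts: int = 5,
    **model_kwargs,
) -> ScrfResults:
    """Fit the ODE response function to ``observed`` driven by ``inp``
    (see :class:`~scrlti.models.ScrfModel`)."""
    model = ScrfModel(observed, inp, priors=priors, **model_kwargs)
    return model.fit(fit_gain=fit_gain, seed=seed, start=start, n_starts=n_starts)


# --------------------------------------------------------------------------
# gain and explained variance
# --------------------------------------------------------------------------


def _pairs(predicted, observed):
    if isinstance(predicted, (TimeSeries, Epoch)):
        predicted = [predicted]
        observed = [observed]
    preds = [np.asarray(p.values if hasattr(p, "values") else p, float) for p in predicted]
    obs = [np.asarray(o.values if hasattr(o, "values") else o, float) for o in observed]
    if len(preds) != len(obs):
        raise InvalidInputError("predicted and observed counts differ")
    for p, o in zip(preds, obs):
        if p.shape != o.shape:
            raise InvalidInputError("predicted/observed length mismatch in an epoch")
    return preds, obs


def estimate_gain(
    predicted,
    observed,
    mode: str = "per_epoch",
    intercept: bool = False,
):
    """Response gain by OLS regression of observation on prediction.

    Slope-only regression through the origin, ``g = <p,o> / <p,p>``, per
    epoch (``mode="per_epoch"``) or over the concatenation of all epochs
    (``mode="fixed"``).  Minimum correction removes the offset an intercept
    would absorb; ``intercept=True`` is available for sensitivity analysis
    (the returned gain is then the slope of a two-parameter OLS).

    Epochs whose prediction has zero energy get gain ``nan``.
    Returns a float in fixed mode, else a numpy array of per-epoch gains.
    """
    if mode not in ("per_epoch", "fixed"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    preds, obs = _pairs(predicted, observed)

    def _slope(p: np.ndarray, o: np.ndarray) -> float:
        if intercept:
            p = p - p.mean()
            o = o - o.mean()
        den = float(p @ p)
        if den == 0.0:
            logger.warning("zero-energy predictor: gain undefined")
            return float("nan")
        return float(p @ o) / den

    if mode == "fixed":
        return _slope(np.concatenate(preds), np.concatenate(obs))
    return np.array([_slope(p, o) for p, o in zip(preds, obs)])


def explained_variance(predicted, observed) -> float:
    """Coefficient of determination
    ``R^2 = 1 - SS_res / SS_tot`` with ``SS_tot = sum (o - mean(o))^2``,
    pooled over epochs when lists are given.  Negative values indicate a
    predictor worse than the observation's mean."""
    preds, obs = _pairs(predicted, observed)
    p = np.concatenate(preds)
    o = np.concatenate(obs)
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("observed signal has zero variance")
    return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot


# --------------------------------------------------------------------------
# variance partitioning
# --------------------------------------------------------------------------


@dataclass
class VariancePartition:
    """Explained-variance fractions at nested response-function levels.

    ``canonical`` is the fraction explained by one response function for
    everybody; ``subject_extra`` the additional fraction explained by one
    response function per subject; ``epoch_extra`` (stimulation data only)
    the further fraction explained by one response function per epoch;
    ``residual`` the rest.  A conservative fallback guarantees that a finer
    level never scores below a coarser one: for any subject (epoch) whose
    specific fit explains less than the coarser fit, the coarser fit's
    residual is used instead.
    """

    canonical: float
    subject_extra: float = 0.0
    epoch_extra: float | None = None
    residual: float = 0.0

    def __post_init__(self) -> None:
        total = self.canonical + self.subject_extra + (self.epoch_extra or 0.0) + self.residual
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"fractions sum to {total}, expected 1")

    def as_dict(self) -> dict:
        d = {
            "canonical": self.canonical,
            "subject_extra": self.subject_extra,
            "residual": self.residual,
        }
        if self.epoch_extra is not None:
            d["epoch_extra"] = self.epoch_extra
        return d


def _pooled_ss_res(preds, obs):
    return sum(float(np.sum((o - p) ** 2)) for p, o in zip(preds, obs))


def variance_partition(
    observed: list,
    predictions_canonical: list,
    predictions_subject: list | None = None,
    predictions_epoch: list | None = None,
    subjects: list | None = None,
) -> VariancePartition:
    """Partition pooled SCR variance across nested response-function levels.

    All prediction lists are aligned with ``observed`` (one entry per
    retained epoch).  ``subjects`` labels each epoch's subject and is
    required when a subject level is present.  Sums of squares are pooled
    over epochs; the conservative fallback is applied per subject (for the
    subject level) and per epoch (for the epoch level).
    """
    _, obs = _pairs(observed, observed)
    preds_c, _ = _pairs(predictions_canonical, observed)
    o_all = np.concatenate(obs)
    ss_tot = float(np.sum((o_all - o_all.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("observed epochs have zero pooled variance")

    ss_res_c = _pooled_ss_res(preds_c, obs)
    r2_c = 1.0 - ss_res_c / ss_tot

    r2_s = r2_c
    ss_res_s_by_epoch = [float(np.sum((o - p) ** 2)) for p, o in zip(preds_c, obs)]
    if predictions_subject is not None:
        if subjects is None:
            raise InvalidInputError("subjects labels required for the subject level")
        preds_s, _ = _pairs(predictions_subject, observed)
        ss_sub = [float(np.sum((o - p) ** 2)) for p, o in zip(preds_s, obs)]
        # conservative fallback per subject: keep the canonical residual when
        # the subject-specific fit is worse for that subject
        by_subject: dict = {}
        for i, s in enumerate(subjects):
            by_subject.setdefault(s, []).append(i)
        chosen = list(ss_res_s_by_epoch)
        for s, idx in by_subject.items():
            if sum(ss_sub[i] for i in idx) < sum(ss_res_s_by_epoch[i] for i in idx):
                for i in idx:
                    chosen[i] = ss_sub[i]
        ss_res_s_by_epoch = chosen
        r2_s = 1.0 - sum(ss_res_s_by_epoch) / ss_tot

    r2_e = None
    if predictions_epoch is not None:
        preds_e, _ = _pairs(predictions_epoch, observed)
        ss_epoch = [float(np.sum((o - p) ** 2)) for p, o in zip(preds_e, obs)]
        chosen = [min(a, b) for a, b in zip(ss_epoch, ss_res_s_by_epoch)]
        r2_e = 1.0 - sum(chosen) / ss_tot

    top = r2_e if r2_e is not None else r2_s
    return VariancePartition(
        canonical=r2_c,
        subject_extra=r2_s - r2_c,
        epoch_extra=(r2_e - r2_s) if r2_e is not None else None,
        residual=1.0 - top,
    )


# --------------------------------------------------------------------------
# reference response function comparison
# --------------------------------------------------------------------------


@dataclass
class ReferenceComparison:
    """Shared variance between an estimated and a reference response
    function, with the alignment shift that was applied."""

    r2: float
    shift_s: float
    slope: float
    intercept: float

    def __float__(self) -> float:
        return self.r2


def compare_scrf_to_reference(
    estimated_ir: TimeSeries,
    reference_ir: TimeSeries,
    allow_shift: bool = True,
    max_shift: float = 5.0,
) -> ReferenceComparison:
    """Regress the estimated impulse response onto a reference one.

    Both responses are resampled to a common grid (the estimated one's
    rate, over the overlap of their supports measured from their own time
    axes).  Because recording-site conduction delays shift responses
    without changing their shape, an optimal integer-sample alignment
    (within ``±max_shift`` seconds, chosen by maximizing R²) is applied
    before the slope+intercept OLS regression; the applied shift is
    reported.
    """
    rate = estimated_ir.rate
    t0 = max(estimated_ir.start, reference_ir.start)
    t1 = min(
        estimated_ir.start + estimated_ir.duration,
        reference_ir.start + reference_ir.duration,
    )
    if t1 <= t0:
        raise InvalidInputError("impulse responses have no overlapping support")
    t = np.arange(t0, t1 + 1e-9, 1.0 / rate)
    a = np.interp(t, estimated_ir.times, estimated_ir.values)
    b = np.interp(t, reference_ir.times, reference_ir.values)
    if np.std(b) == 0 or np.std(a) == 0:
        raise DegenerateInputError("constant impulse response")

    # positive shift: the estimated response lags the reference
    max_lag = int(round(max_shift * rate)) if allow_shift else 0
    best = None
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            aa, bb = a[lag:], b[: len(b) - lag or None]
        else:
            aa, bb = a[: len(a) + lag], b[-lag:]
        if len(aa) < 10 or np.std(aa) == 0 or np.std(bb) == 0:
            continue
        r = float(np.corrcoef(aa, bb)[0, 1])
        r2 = r * r
        if best is None or r2 > best[0]:
            slope = r * np.std(bb) / np.std(aa)
            intercept = float(bb.mean() - slope * aa.mean())
            best = (r2, lag / rate, float(slope), intercept)
    if best is None:
        raise InvalidInputError("no admissible alignment found")
    return ReferenceComparison(*best)


# --------------------------------------------------------------------------
# gain trend
# --------------------------------------------------------------------------


@dataclass
class GainTrend:
    """Linear repetition trend in per-epoch response gains."""

    slope: float
    se: float
    tvalue: float
    pvalue: float
    nobs: int
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            "Gain ~ repetition + subject intercepts (OLS)\n"
            f"  slope {self.slope:10.5f}  SE {self.se:.5f}  "
            f"t {self.tvalue:.3f}  p {self.pvalue:.4g}  n {self.nobs}"
        )


def gain_trend(gains: pd.DataFrame) -> GainTrend:
    """OLS of gain on event repetition with per-subject intercepts.

    ``gains`` needs columns ``gain``, ``repetition`` and ``subject``.  This
    is a deliberate simplification of a mixed-effects analysis: subjects
    enter as fixed intercepts (dummy variables) and the repetition slope is
    shared.  Raises on singular designs, naming the offending columns.
    """
    required = {"gain", "repetition", "subject"}
    if not required.issubset(gains.columns):
        raise InvalidInputError(f"gains frame needs columns {sorted(required)}")
    df = gains.dropna(subset=["gain"]).copy()
    if df["repetition"].nunique() < 2:
        raise InvalidInputError("need at least 2 distinct repetition values")
    dummies = pd.get_dummies(df["subject"].astype(str), prefix="subject", dtype=float)
    X = pd.concat([df[["repetition"]].astype(float), dummies], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise InvalidInputError(
            f"singular design: columns {list(X.columns)} have rank {rank}"
        )
    res = sm.OLS(df["gain"].to_numpy(float), X.to_numpy(float)).fit()
    i = list(X.columns).index("repetition")
    return GainTrend(
        slope=float(res.params[i]),
        se=float(res.bse[i]),
        tvalue=float(res.tvalues[i]),
        pvalue=float(res.pvalues[i]),
        nobs=int(res.nobs),
        params={c: float(v) for c, v in zip(X.columns, res.params)},
    )


# --------------------------------------------------------------------------
# stimulation-rate classes
# --------------------------------------------------------------------------

#: (low upper bound, medium upper bound, exclusion lower bound), Hz.
#: Epochs at the physiologically implausible >= 5 Hz are excluded outright.
RATE_CLASS_THRESHOLDS = (0.12, 0.6, 5.0)


def classify_epochs_by_rate(
    epoch_onsets: list[np.ndarray],
    thresholds: tuple[float, float, float] = RATE_CLASS_THRESHOLDS,
) -> list[str]:
    """Classify stimulation epochs by mean rate.

    ``epoch_onsets`` holds, per epoch, the stimulation onsets (s) falling
    inside it.  The mean rate is ``(n-1) / (last - first)``.  Classes:
    ``low`` below the first threshold, ``high`` above the second,
    ``excluded`` at or above the third, ``medium`` in between, and
    ``undefined`` for epochs with fewer than two onsets.
    """
    lo, hi, excl = thresholds
    if not 0 < lo < hi < excl:
        raise InvalidParameterError("thresholds must be increasing and positive")
    out = []
    for onsets in epoch_onsets:
        onsets = np.asarray(onsets, float)
        if onsets.size < 2 or onsets[-1] <= onsets[0]:
            logger.warning("epoch with <2 onsets: rate undefined")
            out.append("undefined")
            continue
        rate = (onsets.size - 1) / (onsets[-1] - onsets[0])
        if rate >= excl:
            out.append("excluded")
        elif rate > hi:
            out.append("high")
        elif rate < lo:
            out.append("low")
        else:
            out.append("medium")
    return out
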