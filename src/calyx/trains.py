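"""Train-based quantal estimation and short-term depression measures.

During a high-frequency train the readily-releasable pool depletes faster
than it refills, so the cumulative EPSC amplitude approaches a line whose
back-extrapolated intercept at stimulus index 0 estimates the pool amplitude
Nq; the release probability follows as first EPSC / Nq. With replenishment
the intercept overestimates Nq (refill during the steady state inflates the
late cumulative points) — the no-refill limit is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from sklearn.base import BaseEstimator

from .containers import InsufficientDataError


@dataclass
class TrainRecord:
    """One cell's 100 Hz train: per-stimulus amplitudes (nA) plus optional
    recovery test pulses (interval after train end, amplitude)."""

    stim_times: np.ndarray
    amplitudes: np.ndarray
    recovery_tests: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stim_times = np.asarray(self.stim_times, float)
        self.amplitudes = np.asarray(self.amplitudes, float)
        if self.stim_times.shape != self.amplitudes.shape:
            raise ValueError("stim_times and amplitudes must have equal length")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")


@dataclass
class TrainEstimate:
    Nq: float
    p_r: float
    std_ratio: float
    slope: float
    non_estimable: bool = False


def cumulative_curve(train: TrainRecord) -> np.ndarray:
    """Running sum of per-stimulus amplitudes (nondecreasing)."""
    if train.amplitudes.size < 1:
        raise InsufficientDataError("cumulative curve needs >= 1 stimulus")
    return np.cumsum(train.amplitudes)


class CumulativeBackExtrapolation(BaseEstimator):
    """Back-extrapolate the steady-state cumulative amplitude to index 0.

    Parameters
    ----------
    steady_range : tuple of int, default (21, 30)
        First and last stimulus number (1-based, inclusive) of the
        steady-state window used for the straight-line fit; the default
        mirrors the conventional 20-30-EPSC depression window of a
        30-stimulus, 100 Hz train.

    Attributes
    ----------
    Nq_ : float
        Intercept of the line at stimulus index 0 (the "0-time axis"), nA.
    slope_ : float
        Steady-state cumulative growth per stimulus, nA.
    non_estimable_ : bool
        True when the intercept is ~0 (non-depressing train) or negative.
    """

    def __init__(self, steady_range: tuple[int, int] = (21, 30)):
        self.steady_range = steady_range

    def fit(self, cumulative: np.ndarray, y=None) -> "CumulativeBackExtrapolation":
        cum = np.asarray(cumulative, float)
        lo, hi = self.steady_range
        if lo < 1 or hi > cum.size:
            raise ValueError(
                f"steady_range {self.steady_range} outside train of {cum.size} stimuli"
            )
        idx = np.arange(lo, hi + 1, dtype=float)
        y_ss = cum[lo - 1 : hi]
        if idx.size < 2:
            raise InsufficientDataError("back-extrapolation needs >= 2 steady-state points")
        slope, intercept = np.polyfit(idx, y_ss, 1)
        self.slope_ = float(slope)
        self.Nq_ = float(intercept)
        # a constant-amplitude (non-depressing) train extrapolates through 0
        scale = max(float(np.max(np.abs(y_ss))), 1e-30)
        self.non_estimable_ = bool(intercept <= 1e-9 * scale)
        return self

    def release_probability(self, first_amp: float) -> float:
        return estimate_pr_train(self.Nq_, first_amp)


def fit_backextrapolation(
    cumulative: np.ndarray, steady_range: tuple[int, int] = (21, 30)
) -> tuple[float, float]:
    """Functional wrapper: (Nq, slope) from the steady-state cumulative fit."""
    est = CumulativeBackExtrapolation(steady_range=steady_range).fit(cumulative)
    return est.Nq_, est.slope_


def estimate_pr_train(Nq: float, first_amp: float) -> float:
    """Release probability from the first EPSC amplitude divided by Nq."""
    if Nq <= 0:
        raise ValueError("p_r undefined for Nq <= 0")
    return first_amp / Nq


def std_magnitude(train: TrainRecord, window: tuple[int, int] = (20, 30)) -> float:
    """Depression ratio: mean amplitude over ``window`` (1-based, inclusive)
    divided by the first amplitude."""
    lo, hi = window
    if lo < 1 or hi > train.amplitudes.size:
        raise ValueError(f"window {window} outside train of {train.amplitudes.size} stimuli")
    first = train.amplitudes[0]
    if first <= 0:
        raise ValueError("first amplitude must be positive")
    return float(train.amplitudes[lo - 1 : hi].mean() / first)


class RecoveryExponential(BaseEstimator):
    """Single-exponential recovery from depression:
    ``f(t) = 1 - (1 - f0) * exp(-t / tau)``.

    Attributes: ``tau_`` (s), ``f0_`` (fraction immediately after the train),
    ``degenerate_`` (all fractions ~1, no recovery to resolve).
    """

    def fit(self, intervals: np.ndarray, fractions: np.ndarray) -> "RecoveryExponential":
        t = np.asarray(intervals, float)
        f = np.asarray(fractions, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("recovery intervals must be strictly increasing")
        self.degenerate_ = bool(np.allclose(f, 1.0, atol=1e-9))
        if self.degenerate_:
            self.tau_ = np.nan
            self.f0_ = 1.0
            return self

        def model(t, tau, f0):
            return 1.0 - (1.0 - f0) * np.exp(-t / tau)

        p0 = (max(float(np.median(t)), 1e-3), float(np.clip(f[0], 0.0, 0.99)))
        popt, _ = scipy.optimize.curve_fit(
            model, t, f, p0=p0, bounds=([1e-6, 0.0], [np.inf, 1.0]), maxfev=10000
        )
        self.tau_, self.f0_ = float(popt[0]), float(popt[1])
        return self


def recovery_timecourse(
    recovery_tests: list[tuple[float, float]], first_amp: float
) -> dict:
    """Recovery fractions per interval, with a single-exponential fit when
    at least three intervals are available.

    Returns a dict with ``intervals``, ``fractions``, and (when fit)
    ``tau``, ``f0``, ``degenerate``.
    """
    if first_amp <= 0:
        raise ValueError("first amplitude must be positive")
    if not recovery_tests:
        raise InsufficientDataError("no recovery test pulses")
    intervals = np.array([t for t, _ in recovery_tests], float)
    fractions = np.array([a / first_amp for _, a in recovery_tests], float)
    out: dict = {"intervals": intervals, "fractions": fractions}
    if intervals.size >= 3:
        fit = RecoveryExponential().fit(intervals, fractions)
        out.update(tau=fit.tau_, f0=fit.f0_, degenerate=fit.degenerate_)
    return out


def train_estimate(
    train: TrainRecord,
    steady_range: tuple[int, int] = (21, 30),
    std_window: tuple[int, int] = (20, 30),
) -> TrainEstimate:
    """Convenience: full train analysis in one call."""
    cum = cumulative_curve(train)
    back = CumulativeBackExtrapolation(steady_range=steady_range).fit(cum)
    p_r = np.nan if back.non_estimable_ else back.release_probability(train.amplitudes[0])
    return TrainEstimate(
        Nq=back.Nq_,
        p_r=float(p_r),
        std_ratio=std_magnitude(train, std_window),
        slope=back.slope_,
        non_estimable=back.non_estimable_,
    )
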