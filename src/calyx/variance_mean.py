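"""Variance-mean (multiple-probability fluctuation) analysis.

Across conditions of different release probability, the sample variance of
EPSC amplitudes is a parabolic function of the mean amplitude under a simple
binomial release model:

    sigma^2 = q * I - I^2 / N

where I is the mean amplitude, q the mean quantal size and N the number of
release sites. q is the initial slope of the parabola, Nq its x-intercept,
and the release probability at a reference condition is p_r = I_ref / (N q).

The model is linear in (q, 1/N) over the monomials (I, -I^2), so the fit is a
non-negative linear least-squares problem with no iterative-optimiser
ambiguity. Points consistent with a straight line through the origin
(curvature <= 0, the low-p_r regime) give q from the slope and an unbounded-N
flag instead of a number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize
from sklearn.base import BaseEstimator

from .containers import AmplitudeSeries, InsufficientDataError


@dataclass
class VMPoint:
    """One condition's (mean, variance) summary of EPSC amplitudes (nA, nA^2)."""

    I: float
    var: float
    n: int
    condition_label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError("a variance-mean point needs >= 2 sweeps")
        if self.var < 0:
            raise ValueError("variance cannot be negative")


@dataclass
class QuantalEstimate:
    """Quantal parameters from a parabola fit.

    ``N`` may be ``inf`` when the points carry no curvature (low-p_r regime);
    ``p_r_gt_1`` flags a reference amplitude exceeding the pool estimate.
    """

    q: float
    N: float
    Nq: float
    p_r: float
    residual_ss: float
    n_points: int
    p_r_gt_1: bool = False
    N_unbounded: bool = False


def summarize_condition(series: AmplitudeSeries) -> VMPoint:
    """Mean and unbiased (n-1) sample variance of one condition, in nA / nA^2."""
    amps = series.in_nA()
    if amps.size < 2:
        raise InsufficientDataError(
            f"need >= 2 sweeps to form a variance-mean point, got {amps.size}"
        )
    return VMPoint(
        I=float(amps.mean()),
        var=float(amps.var(ddof=1)),
        n=amps.size,
        condition_label=series.condition_label,
    )


class VarianceMeanAnalysis(BaseEstimator):
    """Fit the variance-mean parabola ``var = q*I - I**2/N``.

    Parameters
    ----------
    weighted : bool, default False
        Weight points by the inverse variance-of-variance ``2*var^2/(n-1)``
        instead of the default unweighted least squares.

    Attributes
    ----------
    q_ : float
        Quantal size (nA), the initial slope of the parabola.
    N_ : float
        Number of release sites; ``inf`` when the points have no curvature.
    Nq_ : float
        Pool amplitude (nA), the parabola's x-intercept (``inf`` with N).
    residual_ss_ : float
        Sum of squared residuals of the fit.
    N_unbounded_ : bool
        True when curvature <= 0 and only q is identifiable.
    """

    def __init__(self, weighted: bool = False):
        self.weighted = weighted

    def fit(self, points: list[VMPoint] | np.ndarray, y=None) -> "VarianceMeanAnalysis":
        if len(points) and isinstance(points[0], VMPoint):
            I = np.array([p.I for p in points], float)
            var = np.array([p.var for p in points], float)
            n = np.array([p.n for p in points], float)
        else:
            arr = np.asarray(points, float)
            I, var = arr[:, 0], arr[:, 1]
            n = arr[:, 2] if arr.shape[1] > 2 else np.full(I.shape, 15.0)
        if np.unique(I).size < 3:
            raise InsufficientDataError("parabola fit needs >= 3 points with distinct means")

        w = np.ones_like(I)
        if self.weighted:
            varvar = 2.0 * np.maximum(var, 1e-12) ** 2 / (n - 1.0)
            w = 1.0 / np.sqrt(varvar)

        # linear in (q, 1/N): var = q*I + (1/N)*(-I^2); NNLS keeps both >= 0
        A = np.column_stack([I, -(I**2)]) * w[:, None]
        coef, _ = scipy.optimize.nnls(A, var * w)
        q, inv_N = coef
        if inv_N <= 0 or not np.isfinite(inv_N):
            # no curvature: straight line through the origin, slope = q
            self.N_unbounded_ = True
            q = float(np.sum(w**2 * I * var) / np.sum(w**2 * I**2))
            self.N_ = np.inf
        else:
            self.N_unbounded_ = False
            self.N_ = float(1.0 / inv_N)
        self.q_ = float(q)
        self.Nq_ = self.q_ * self.N_
        pred = self.predict(I)
        self.residual_ss_ = float(np.sum((var - pred) ** 2))
        self.n_points_ = int(I.size)
        return self

    def predict(self, I: np.ndarray) -> np.ndarray:
        """Model variance at mean amplitude(s) I."""
        I = np.asarray(I, float)
        curv = 0.0 if np.isinf(self.N_) else 1.0 / self.N_
        return self.q_ * I - curv * I**2

    def release_probability(self, I_ref: float) -> float:
        """p_r at the reference condition: I_ref / (N q)."""
        est = derive_parameters(self.q_, self.N_, I_ref)
        return est.p_r


def fit_parabola(points: list[VMPoint], weighted: bool = False) -> tuple[float, float, float]:
    """Functional wrapper: returns (q, N, residual_ss); N is inf when unbounded."""
    est = VarianceMeanAnalysis(weighted=weighted).fit(points)
    return est.q_, est.N_, est.residual_ss_


def derive_parameters(q: float, N: float, I_ref: float) -> QuantalEstimate:
    """Pool size Nq and reference release probability p_r = I_ref / Nq."""
    if q <= 0 or N <= 0:
        raise ValueError("q and N must be positive")
    Nq = q * N
    if Nq == 0:
        raise ZeroDivisionError("Nq = 0: p_r undefined")
    p_r = I_ref / Nq
    gt1 = p_r > 1.0
    if gt1:
        warnings.warn(
            f"reference amplitude {I_ref} exceeds pool estimate Nq={Nq}: p_r > 1",
            stacklevel=2,
        )
    return QuantalEstimate(
        q=q, N=N, Nq=Nq, p_r=p_r, residual_ss=np.nan, n_points=0,
        p_r_gt_1=gt1, N_unbounded=bool(np.isinf(N)),
    )


def percent_change(before: float, after: float) -> float:
    """Percent reduction 100*(before - after)/before, to one decimal place."""
    if before == 0:
        raise ZeroDivisionError("percent change undefined for a zero baseline")
    return round(100.0 * (before - after) / before, 1)
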