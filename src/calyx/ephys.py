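"""Action-potential waveform features, I-V curves, decay kinetics, rheobase,
and the AP-overshoot -> EPSC safety-margin (plateau-breakpoint) relation.

Conventions: membrane potential in mV, time in s, currents in nA with inward
current negative in storage (magnitudes are used for inhibition percentages).
The AP threshold is the voltage at the first sample where dV/dt reaches the
criterion (default 50 V/s); the depolarising afterpotential (DAP) is the
local maximum after fast repolarisation, within 5 ms of the AP peak, minus
the resting potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
from sklearn.base import BaseEstimator

from .containers import Trace


@dataclass
class ApFeatures:
    rmp: float
    peak: float
    amplitude: float  # peak - rmp
    overshoot: float  # peak above 0 mV
    half_width: float  # ms, width at rmp + amplitude/2
    dap: float  # mV above rmp; nan if absent
    threshold_mV: float  # nan if criterion never reached
    has_ap: bool = True


@dataclass
class IVCurve:
    step_mV: np.ndarray
    peak_current_nA: np.ndarray  # signed; inward negative

    def __post_init__(self) -> None:
        self.step_mV = np.asarray(self.step_mV, float)
        self.peak_current_nA = np.asarray(self.peak_current_nA, float)
        if self.step_mV.shape != self.peak_current_nA.shape:
            raise ValueError("step and current arrays must have equal length")
        if self.step_mV.size >= 2 and not np.all(np.diff(self.step_mV) > 0):
            raise ValueError("voltage steps must be strictly increasing")


def _interp_crossing(t0, t1, v0, v1, level):
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_features(
    vm: Trace,
    stim_time: float,
    dvdt_criterion: float = 50.0,
    baseline_window: float = 0.002,
    dap_window_ms: float = 5.0,
    min_amplitude: float = 20.0,
) -> ApFeatures:
    """Extract features of a single AP following ``stim_time``.

    ``dvdt_criterion`` is in V/s. An event smaller than ``min_amplitude`` mV
    above rest is reported as a no-AP result rather than an error.
    """
    t, v = vm.times, vm.values
    pre = (t >= stim_time - baseline_window) & (t < stim_time)
    rmp = float(v[pre].mean()) if np.any(pre) else float(v[t < stim_time].mean())
    post = t >= stim_time
    tp, vp = t[post], v[post]
    i_peak = int(np.argmax(vp))
    peak = float(vp[i_peak])
    amplitude = peak - rmp
    if amplitude < min_amplitude:
        return ApFeatures(rmp, peak, amplitude, max(peak, 0.0), np.nan, np.nan, np.nan, has_ap=False)

    # half-width at rmp + amplitude/2, linearly interpolated on both flanks
    level = rmp + amplitude / 2.0
    above = vp >= level
    rising = np.nonzero(above[: i_peak + 1])[0]
    t_up = tp[0] if rising.size == 0 or rising[0] == 0 else _interp_crossing(
        tp[rising[0] - 1], tp[rising[0]], vp[rising[0] - 1], vp[rising[0]], level
    )
    falling = np.nonzero(~above[i_peak:])[0]
    if falling.size == 0:
        t_down = tp[-1]
    else:
        j = i_peak + falling[0]
        t_down = _interp_crossing(tp[j - 1], tp[j], vp[j - 1], vp[j], level)
    half_width = (t_down - t_up) * 1e3

    # threshold: first dV/dt >= criterion between stimulus and peak
    dvdt = np.gradient(vp, tp) / 1e3  # mV/s -> V/s
    hits = np.nonzero(dvdt[: i_peak + 1] >= dvdt_criterion)[0]
    threshold = float(vp[hits[0]]) if hits.size else np.nan

    # DAP: local max after fast repolarisation, within dap_window_ms of peak
    dap = np.nan
    win = (tp > t_down) & (tp <= tp[i_peak] + dap_window_ms / 1e3)
    if np.any(win):
        seg = vp[win]
        i_min = int(np.argmin(seg[: max(1, seg.size // 2)]))
        after = seg[i_min:]
        if after.size:
            dap = float(after.max() - rmp)

    return ApFeatures(
        rmp=rmp, peak=peak, amplitude=amplitude, overshoot=peak if peak > 0 else 0.0,
        half_width=float(half_width), dap=dap, threshold_mV=threshold,
    )


def iv_curve(sweeps: list[tuple[float, Trace]], window: tuple[float, float] | None = None) -> IVCurve:
    """Per-step peak current: the extremum of largest magnitude (signed)
    within the pulse window (default: whole trace)."""
    if len(sweeps) < 2:
        raise ValueError("an I-V curve needs >= 2 steps")
    sweeps = sorted(sweeps, key=lambda s: s[0])
    steps, peaks = [], []
    for step_mV, trace in sweeps:
        tr = trace if window is None else trace.window(*window)
        vals = tr.values
        peaks.append(float(vals[np.argmax(np.abs(vals))]) if vals.size else 0.0)
        steps.append(step_mV)
    return IVCurve(np.array(steps), np.array(peaks))


def inhibition_profile(
    ctrl: IVCurve, drug: IVCurve, floor_frac: float = 0.05
) -> dict:
    """Per-step percent inhibition 100*(1 - |I_drug|/|I_ctrl|) and its maximum.

    Steps where |I_ctrl| is below ``floor_frac`` of the largest control
    current are excluded (near-zero denominators are meaningless).
    """
    if ctrl.step_mV.shape != drug.step_mV.shape or not np.allclose(ctrl.step_mV, drug.step_mV):
        raise ValueError("control and drug curves must share the same voltage steps")
    mag_c = np.abs(ctrl.peak_current_nA)
    mag_d = np.abs(drug.peak_current_nA)
    floor = floor_frac * mag_c.max() if mag_c.size else 0.0
    valid = mag_c > floor
    inhib = np.full(mag_c.shape, np.nan)
    inhib[valid] = 100.0 * (1.0 - mag_d[valid] / mag_c[valid])
    return {
        "step_mV": ctrl.step_mV,
        "inhibition_pct": inhib,
        "max_inhibition_pct": float(np.nanmax(inhib)) if np.any(valid) else np.nan,
    }


class ExponentialDecay(BaseEstimator):
    """Single-exponential decay fit y = A * exp(-t / tau) (+ optional offset).

    ``tau_`` is in the unit of the supplied time axis. A segment with no
    decay sets ``infinite_tau_``.
    """

    def __init__(self, fit_offset: bool = False):
        self.fit_offset = fit_offset

    def fit(self, t: np.ndarray, y: np.ndarray) -> "ExponentialDecay":
        t = np.asarray(t, float)
        y = np.asarray(y, float)
        span = float(y.max() - y.min())
        self.infinite_tau_ = span <= 1e-12 * max(abs(float(y.max())), 1.0)
        if self.infinite_tau_:
            self.tau_ = np.inf
            self.amplitude_ = 0.0
            self.offset_ = float(y.mean())
            return self
        t0 = t - t[0]
        if self.fit_offset:
            def model(t, A, tau, c):
                return A * np.exp(-t / tau) + c
            p0 = (span, max((t0[-1] - t0[0]) / 3.0, 1e-12), float(y.min()))
        else:
            def model(t, A, tau):
                return A * np.exp(-t / tau)
            p0 = (float(y[0]), max((t0[-1] - t0[0]) / 3.0, 1e-12))
        popt, _ = scipy.optimize.curve_fit(model, t0, y, p0=p0, maxfev=20000)
        self.amplitude_ = float(popt[0])
        self.tau_ = float(popt[1])
        self.offset_ = float(popt[2]) if self.fit_offset else 0.0
        return self


def exp_decay_tau(t: np.ndarray, y: np.ndarray) -> float:
    """Decay time constant of a monotone-decaying segment (inf if constant)."""
    return ExponentialDecay().fit(t, y).tau_


def rheobase(steps: list[tuple[float, Trace]], detector) -> dict:
    """Smallest injected current (pA) whose sweep fires >= 1 detected AP.

    ``detector`` maps a Trace to an EventSeries (e.g.
    ``transmission.detect_spikes`` with chosen threshold/refractory).
    Returns ``{"rheobase_pA": value-or-nan, "reached": bool}``.
    """
    for current_pA, trace in sorted(steps, key=lambda s: s[0]):
        if len(detector(trace)) >= 1:
            return {"rheobase_pA": float(current_pA), "reached": True}
    return {"rheobase_pA": np.nan, "reached": False}


class PlateauBreakpoint(BaseEstimator):
    """Safety-margin model: EPSC (normalised) stays at 1 until the AP
    overshoot drops below a breakpoint b, then declines linearly:

        y(x) = 1                 for x >= b
        y(x) = 1 - s * (b - x)   for x <  b   (s >= 0)

    Fit by deterministic grid search over b (candidates: observed overshoots
    plus a uniform grid) with s solved in closed form at each b.

    Attributes: ``breakpoint_`` (mV), ``slope_`` (per mV), ``censored_``
    (no decline observed; breakpoint censored at the smallest overshoot).
    """

    def __init__(self, n_grid: int = 401):
        self.n_grid = n_grid

    @staticmethod
    def _sse(x, y, b):
        below = x < b
        if not np.any(below):
            return float(np.sum((y - 1.0) ** 2)), 0.0
        d = b - x[below]
        s = float(np.sum((1.0 - y[below]) * d) / np.sum(d * d))
        s = max(s, 0.0)
        resid_below = y[below] - (1.0 - s * d)
        resid_above = y[~below] - 1.0
        return float(np.sum(resid_below**2) + np.sum(resid_above**2)), s

    def fit(self, overshoot: np.ndarray, epsc_norm: np.ndarray) -> "PlateauBreakpoint":
        x = np.asarray(overshoot, float)
        y = np.asarray(epsc_norm, float)
        if x.size < 5:
            raise ValueError("breakpoint fit needs >= 5 (overshoot, EPSC) pairs")
        if np.all(y >= 1.0 - 1e-9):
            self.breakpoint_ = float(x.min())
            self.slope_ = 0.0
            self.censored_ = True
            self.plateau_ = 1.0
            return self
        candidates = np.union1d(np.unique(x), np.linspace(x.min(), x.max(), self.n_grid))
        best = min((self._sse(x, y, b) + (b,) for b in candidates), key=lambda r: r[0])
        sse, s, b = best
        self.breakpoint_ = float(b)
        self.slope_ = float(s)
        self.censored_ = False
        self.plateau_ = 1.0
        self.residual_ss_ = float(sse)
        return self

    def predict(self, overshoot):
        x = np.asarray(overshoot, float)
        return np.where(x >= self.breakpoint_, 1.0, 1.0 - self.slope_ * (self.breakpoint_ - x))


def safety_margin(pairs: list[tuple[float, float]]) -> dict:
    """Plateau-breakpoint summary of (overshoot, normalised EPSC) pairs."""
    x = np.array([p[0] for p in pairs], float)
    y = np.array([p[1] for p in pairs], float)
    fit = PlateauBreakpoint().fit(x, y)
    return {
        "breakpoint_mV": fit.breakpoint_,
        "plateau": fit.plateau_,
        "slope_per_mV": fit.slope_,
        "censored": fit.censored_,
    }
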