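"""Synthetic ground-truth data for every analysis stage.

Each generator emulates the statistical structure one estimator assumes:

* binomial quantal EPSC amplitudes at a set release probability,
* depletion-driven short-term depression trains with exponential refill,
* Hill-shaped dose-response samples,
* capacitance jumps with mono-exponential (half-life parameterised) decay,
* square-pulse Ca2+ currents with known charge integral,
* paired pre/postsynaptic spike trains with independent transmission failures,
* photostimulus-locked unit rasters (Poisson background, trans-synaptic or
  collision-sensitive antidromic responses),
* two-state (Up/Down) membrane-potential traces.

RNG contract: one root seed on :class:`SimConfig`; each generator call draws a
child stream in call order, so a pipeline replayed from a fresh ``SimConfig``
with the same seed and call order is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import AmplitudeSeries, EventSeries, Trace


@dataclass
class SimConfig:
    """Simulation plumbing: root seed, sweep count, trace sampling rate."""

    seed: int
    n_sweeps: int = 15
    sampling_rate: float = 50_000.0

    _ss: np.random.SeedSequence = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        self._ss = np.random.SeedSequence(self.seed)

    def rng(self) -> np.random.Generator:
        """Child generator; successive calls yield independent streams."""
        return np.random.default_rng(self._ss.spawn(1)[0])


@dataclass
class ReleaseModelParams:
    """Binomial release model: N sites, release probability p_r, quantal size q (pA)."""

    N: int
    p_r: float
    q: float
    cv_q: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_r <= 1.0:
            raise ValueError("p_r must lie in [0, 1]")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.q <= 0:
            raise ValueError("q must be positive")
        if self.cv_q < 0:
            raise ValueError("cv_q must be >= 0")


@dataclass
class DepletionParams:
    """Depletion model for 100 Hz trains: exponential refill toward N."""

    release: ReleaseModelParams
    tau_rec: float  # s; math.inf = no replenishment
    isi: float = 0.01
    n_stim: int = 30

    def __post_init__(self) -> None:
        if not (self.tau_rec > 0 or math.isinf(self.tau_rec)):
            raise ValueError("tau_rec must be positive or infinite")
        if self.n_stim < 1:
            raise ValueError("n_stim must be >= 1")
        if self.isi <= 0:
            raise ValueError("isi must be positive")


def _quantal_sum(rng: np.random.Generator, k: int, q: float, cv_q: float) -> float:
    """Sum of k per-quantum amplitudes q*(1 + cv_q*z), truncated positive."""
    if k == 0:
        return 0.0
    if cv_q == 0.0:
        return k * q
    amps = q * (1.0 + cv_q * rng.standard_normal(k))
    # amplitudes are physical magnitudes: resample any non-positive draw
    while np.any(amps <= 0):
        bad = amps <= 0
        amps[bad] = q * (1.0 + cv_q * rng.standard_normal(int(bad.sum())))
    return float(amps.sum())


def gen_epsc_samples(params: ReleaseModelParams, cfg: SimConfig) -> AmplitudeSeries:
    """Per-sweep EPSC amplitudes from a binomial release model (pA)."""
    rng = cfg.rng()
    k = rng.binomial(params.N, params.p_r, size=cfg.n_sweeps)
    if params.cv_q == 0.0:
        amps = k * params.q
    else:
        amps = np.array([_quantal_sum(rng, int(ki), params.q, params.cv_q) for ki in k])
    return AmplitudeSeries(amps, unit="pA")


def gen_std_train(
    params: DepletionParams, cfg: SimConfig, expected: bool = False
) -> AmplitudeSeries:
    """Short-term-depression train from pool depletion with exponential refill.

    Pool starts full (N sites). Each stimulus releases Binomial(available, p_r)
    quanta (or the expectation, in ``expected`` mode); between stimuli the pool
    relaxes toward N as ``N - (N - n) * exp(-isi / tau_rec)``.
    """
    rel = params.release
    rng = cfg.rng()
    refill = 0.0 if math.isinf(params.tau_rec) else 1.0 - math.exp(-params.isi / params.tau_rec)
    amps = np.empty(params.n_stim)
    pool = float(rel.N)
    for i in range(params.n_stim):
        if expected:
            released = pool * rel.p_r
        else:
            released = float(rng.binomial(int(round(pool)), rel.p_r))
        amps[i] = released * rel.q
        pool -= released
        pool += (rel.N - pool) * refill
        pool = min(pool, float(rel.N))
    return AmplitudeSeries(amps, unit="pA")


def gen_recovery_tests(
    params: DepletionParams,
    intervals,
    cfg: SimConfig,
    expected: bool = False,
) -> list[tuple[float, float]]:
    """Recovery test pulses after a depleting train.

    The pool is depleted by the expected-value train; for each interval the
    pool recovers toward N as ``N - (N - n_end)*exp(-t/tau_rec)`` and one test
    stimulus releases (each interval models an independently re-depleted
    trial). Returns ``[(interval_s, amplitude_pA), ...]``.
    """
    rel = params.release
    rng = cfg.rng()
    # expected-value depletion to the end-of-train pool
    refill = 0.0 if math.isinf(params.tau_rec) else 1.0 - math.exp(-params.isi / params.tau_rec)
    pool = float(rel.N)
    for _ in range(params.n_stim):
        pool -= pool * rel.p_r
        pool += (rel.N - pool) * refill
    out = []
    for t in np.asarray(intervals, float):
        if math.isinf(params.tau_rec):
            n_rec = pool
        else:
            n_rec = rel.N - (rel.N - pool) * math.exp(-t / params.tau_rec)
        if expected:
            released = n_rec * rel.p_r
        else:
            released = float(rng.binomial(int(round(n_rec)), rel.p_r))
        out.append((float(t), released * rel.q))
    return out


def gen_dose_response(
    concs,
    ec50: float,
    max_block: float,
    hill: float,
    noise_sd: float,
    cfg: SimConfig,
    n_cells: int = 8,
):
    """Per-cell fractional-block samples on a Hill curve, as a tidy table.

    Returns a pandas DataFrame with columns cell_id, conc_mM, block_pct;
    block = Hill(conc) + Gaussian noise, clipped to [0, 100].
    """
    import pandas as pd

    concs = np.asarray(concs, dtype=float)
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive")
    rng = cfg.rng()
    rows = []
    for conc in concs:
        y = max_block - max_block / (1.0 + (conc / ec50) ** hill)
        blocks = np.clip(y + noise_sd * rng.standard_normal(n_cells), 0.0, 100.0)
        for cell, b in enumerate(blocks):
            rows.append((f"cell{cell:02d}", conc, b))
    return pd.DataFrame(rows, columns=["cell_id", "conc_mM", "block_pct"])


def gen_cm_trace(
    dcm: float,
    half_decay: float,
    cfg: SimConfig,
    baseline: float = 15.0,
    pulse_end: float = 1.0,
    duration: float = 30.0,
    sampling_rate: float = 1000.0,
    noise_sd: float = 0.0,
    artifact_pF: float = 0.0,
) -> Trace:
    """Capacitance trace: flat baseline, jump of ``dcm`` pF at ``pulse_end``,
    then decay ``dcm * 2**(-(t - pulse_end)/half_decay)`` (endocytosis).

    An optional artifact transient (``artifact_pF``, decaying with a 100 ms
    half-life) is confined to the first 450 ms after the pulse, emulating the
    non-exocytic capacitance contamination the measurement window avoids.
    """
    if duration < pulse_end + 0.5:
        raise ValueError("trace must span at least 500 ms after pulse_end")
    rng = cfg.rng()
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    cm = np.full(n, baseline)
    post = t >= pulse_end
    dt = t[post] - pulse_end
    cm[post] += dcm * 2.0 ** (-dt / half_decay)
    if artifact_pF:
        art = t >= pulse_end
        dta = t[art] - pulse_end
        bump = artifact_pF * 2.0 ** (-dta / 0.1)
        # strictly confined to the excluded window (half-sample guard against
        # float round-off putting the boundary sample on the wrong side)
        bump[dta >= 0.45 - 0.5 / sampling_rate] = 0.0
        cm[art] += bump
    if noise_sd:
        cm = cm + noise_sd * rng.standard_normal(n)
    return Trace(t, cm, sampling_rate=sampling_rate, unit="pF")


def gen_ca_current(
    amp: float,
    dur_ms: float,
    cfg: SimConfig,
    rise_tau_ms: float = 0.0,
    pad_ms: float = 5.0,
) -> Trace:
    """Square inward Ca2+ current pulse (nA, inward negative), optional
    exponential rise; the charge over the pulse window has the closed form
    ``amp * (dur - tau*(1 - exp(-dur/tau)))`` (in nA*ms = pC)."""
    rate = cfg.sampling_rate
    total_s = (dur_ms + 2 * pad_ms) / 1e3
    n = int(round(total_s * rate))
    t = np.arange(n) / rate
    i = np.zeros(n)
    t0, t1 = pad_ms / 1e3, (pad_ms + dur_ms) / 1e3
    inside = (t >= t0) & (t < t1)
    if rise_tau_ms > 0:
        tau = rise_tau_ms / 1e3
        i[inside] = -amp * (1.0 - np.exp(-(t[inside] - t0) / tau))
    else:
        i[inside] = -amp
    return Trace(t, i, sampling_rate=rate, unit="nA")


def gen_paired_spikes(
    freq: float,
    n_stim: int,
    p_fail: float,
    cfg: SimConfig,
    latency_ms: float = 1.0,
    jitter_sd_ms: float = 0.1,
) -> tuple[EventSeries, EventSeries]:
    """Regular presynaptic train; each AP transmits independently with
    probability 1 - p_fail at ``latency_ms`` (+ Gaussian jitter)."""
    if not 0.0 <= p_fail <= 1.0:
        raise ValueError("p_fail must lie in [0, 1]")
    rng = cfg.rng()
    pre = np.arange(n_stim) / freq
    transmitted = rng.random(n_stim) >= p_fail
    post = pre[transmitted] + (latency_ms + jitter_sd_ms * rng.standard_normal(int(transmitted.sum()))) / 1e3
    return EventSeries(pre, label="pre"), EventSeries(np.sort(post), label="post")


def gen_unit_raster(
    r_spont: float,
    stim_times,
    p_evoked: float,
    cfg: SimConfig,
    evoked_window_ms: tuple[float, float] = (5.0, 25.0),
    mode: str = "trans-synaptic",
    antidromic_latency_ms: float = 5.0,
    antidromic_jitter_ms: float = 0.2,
    collision_window_ms: float = 10.0,
    duration: float | None = None,
    background_times=None,
) -> tuple[EventSeries, EventSeries]:
    """Photostimulus-locked unit raster.

    Homogeneous Poisson background at ``r_spont``. ``trans-synaptic`` mode adds
    at most one evoked spike per stimulus, uniformly inside the evoked window,
    with probability ``p_evoked`` (independent of preceding activity).
    ``antidromic`` mode adds a fixed-latency spike that is deleted whenever a
    background spike occurred within ``collision_window_ms`` before the
    stimulus (spike collision in the axon).
    """
    if mode not in ("trans-synaptic", "antidromic"):
        raise ValueError(f"unknown raster mode {mode!r}")
    rng = cfg.rng()
    stim = np.sort(np.asarray(stim_times, dtype=float))
    if duration is None:
        duration = float(stim[-1]) + 1.0 if stim.size else 1.0
    if background_times is not None:
        background = np.sort(np.asarray(background_times, float))
    elif r_spont > 0:
        n_bg = rng.poisson(r_spont * duration)
        background = np.sort(rng.uniform(0.0, duration, n_bg))
    else:
        background = np.empty(0)
    lo, hi = evoked_window_ms
    fires = rng.random(stim.size) < p_evoked
    if mode == "trans-synaptic":
        evoked = stim[fires] + rng.uniform(lo, hi, int(fires.sum())) / 1e3
    else:
        collided = (
            np.searchsorted(background, stim)
            - np.searchsorted(background, stim - collision_window_ms / 1e3)
        ) > 0
        keep = fires & ~collided
        evoked = stim[keep] + (
            antidromic_latency_ms + antidromic_jitter_ms * rng.standard_normal(int(keep.sum()))
        ) / 1e3
    spikes = EventSeries(np.concatenate([background, np.asarray(evoked)]), label="spikes")
    return spikes, EventSeries(stim, label="stim")


def gen_vm_trace(
    down_mV: float,
    up_mV: float,
    dwell_down_s: float,
    dwell_up_s: float,
    noise_sd_mV: float,
    duration: float,
    cfg: SimConfig,
    sampling_rate: float = 1000.0,
) -> Trace:
    """Two-state (Up/Down) membrane-potential telegraph process with
    exponential dwell times plus additive Gaussian noise."""
    rng = cfg.rng()
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    vm = np.full(n, down_mV)
    if dwell_up_s > 0:
        state_up = False
        pos = 0.0
        while pos < duration:
            dwell = rng.exponential(dwell_up_s if state_up else dwell_down_s)
            if state_up:
                i0 = int(pos * sampling_rate)
                i1 = min(int((pos + dwell) * sampling_rate), n)
                vm[i0:i1] = up_mV
            pos += dwell
            state_up = not state_up
    if noise_sd_mV:
        vm = vm + noise_sd_mV * rng.standard_normal(n)
    return Trace(t, vm, sampling_rate=sampling_rate, unit="mV")


def gen_ap_trace(
    cfg: SimConfig,
    rmp: float = -70.0,
    peak: float = 46.7,
    half_width_ms: float = 0.28,
    dap_mV: float = 5.98,
    stim_time: float = 0.005,
    duration: float = 0.02,
    noise_sd_mV: float = 0.0,
) -> Trace:
    """Single stylised action potential: Gaussian spike of known peak and
    half-width riding on the resting potential, followed by a slower
    depolarising afterpotential bump of known amplitude."""
    rng = cfg.rng()
    rate = cfg.sampling_rate
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    # Gaussian spike: FWHM = half_width -> sigma = fwhm / (2 sqrt(2 ln 2))
    sigma = (half_width_ms / 1e3) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    t_peak = stim_time + 4.0 * sigma
    vm = rmp + (peak - rmp) * np.exp(-0.5 * ((t - t_peak) / sigma) ** 2)
    # DAP: slow Gaussian bump centred 3 ms after the spike peak (far enough
    # that spike and bump overlap negligibly at each other's maxima)
    sigma_dap = 1.0e-3
    vm += dap_mV * np.exp(-0.5 * ((t - (t_peak + 3e-3)) / sigma_dap) ** 2)
    if noise_sd_mV:
        vm = vm + noise_sd_mV * rng.standard_normal(n)
    return Trace(t, vm, sampling_rate=rate, unit="mV")
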