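"""Spike-transmission fidelity (paired recordings) and the in-vivo unit
pipeline: PSTH, unit inclusion, antidromic collision test, evoked-rate
subtraction, relative fidelity, and Up/Down membrane-potential histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EventSeries, Trace


@dataclass
class UnitRaster:
    """Spike and stimulus times for one unit in one behavioural state."""

    unit_id: str
    spike_times: np.ndarray
    stim_times: np.ndarray
    state_label: str = "awake"  # awake | anesthetized
    stim_rate: float = 0.2  # Hz

    def __post_init__(self) -> None:
        self.spike_times = np.sort(np.asarray(self.spike_times, float))
        self.stim_times = np.sort(np.asarray(self.stim_times, float))


@dataclass
class FidelityResult:
    n_pre: int
    n_transmitted: int
    fidelity: float  # %
    frequency: float  # Hz

    def __post_init__(self) -> None:
        if not 0 <= self.n_transmitted <= self.n_pre:
            raise ValueError("transmitted count must lie in [0, n_pre]")


def detect_spikes(vm: Trace, threshold_mV: float = -20.0, refractory_ms: float = 1.0) -> EventSeries:
    """Upward threshold crossings with refractory enforcement; event times at
    the waveform peak following each crossing."""
    v = vm.values
    t = vm.times
    up = np.nonzero((v[1:] >= threshold_mV) & (v[:-1] < threshold_mV))[0] + 1
    times = []
    last = -np.inf
    refr = refractory_ms / 1e3
    for i in up:
        if t[i] - last < refr:
            continue
        # peak = local max until the trace falls back below threshold
        j = i
        while j + 1 < v.size and v[j + 1] >= threshold_mV:
            j += 1
        k = i + int(np.argmax(v[i : j + 1]))
        times.append(t[k])
        last = t[i]
    return EventSeries(np.array(times), label="spikes")


def match_fidelity(
    pre: EventSeries,
    post: EventSeries,
    latency_window_ms: tuple[float, float] = (0.2, 3.0),
    frequency: float | None = None,
) -> FidelityResult:
    """Greedy one-to-one matching of each presynaptic AP to at most one
    postsynaptic AP within the latency window after it.

    The window must be shorter than the presynaptic inter-spike interval,
    otherwise matching is ambiguous.
    """
    lo, hi = (w / 1e3 for w in latency_window_ms)
    if not 0 < lo < hi:
        raise ValueError("latency window must be positive with lo < hi")
    if len(pre) >= 2:
        min_isi = float(np.min(np.diff(pre.times)))
        if hi >= min_isi:
            raise ValueError(
                f"latency window {latency_window_ms} ms is not shorter than the "
                f"presynaptic ISI ({min_isi * 1e3:.3g} ms): matching is ambiguous"
            )
    if frequency is None:
        frequency = 1.0 / min_isi if len(pre) >= 2 else np.nan
    matched = 0
    j = 0
    post_t = post.times
    for tp in pre.times:
        while j < post_t.size and post_t[j] < tp + lo:
            j += 1
        if j < post_t.size and post_t[j] <= tp + hi:
            matched += 1
            j += 1  # each postsynaptic AP used at most once
    n_pre = len(pre)
    return FidelityResult(
        n_pre=n_pre,
        n_transmitted=matched,
        fidelity=100.0 * matched / n_pre if n_pre else 0.0,
        frequency=float(frequency),
    )


def psth(
    raster: UnitRaster, bin_ms: float = 5.0, range_ms: tuple[float, float] = (-50.0, 100.0)
) -> dict:
    """Stimulus-aligned histogram of spike counts.

    Returns bin edges/centers (ms), counts summed over stimuli, and rates
    in Hz (counts / (n_stim * bin width)).
    """
    lo, hi = range_ms
    if (hi - lo) % bin_ms not in (0, bin_ms):
        raise ValueError("bin width must divide the PSTH range")
    n_bins = int(round((hi - lo) / bin_ms))
    edges = lo + bin_ms * np.arange(n_bins + 1)
    offsets = []
    for s in raster.stim_times:
        d = (raster.spike_times - s) * 1e3
        offsets.append(d[(d >= lo) & (d < hi)])
    all_off = np.concatenate(offsets) if offsets else np.empty(0)
    counts, _ = np.histogram(all_off, bins=edges)
    n_stim = max(raster.stim_times.size, 1)
    return {
        "edges_ms": edges,
        "centers_ms": edges[:-1] + bin_ms / 2.0,
        "counts": counts,
        "rate_Hz": counts / (n_stim * bin_ms / 1e3),
        "n_stim": raster.stim_times.size,
    }


def _window_counts(spikes: np.ndarray, anchors: np.ndarray, lo_s: float, hi_s: float) -> np.ndarray:
    """Spike counts in [anchor+lo, anchor+hi) for every anchor."""
    return np.searchsorted(spikes, anchors + hi_s) - np.searchsorted(spikes, anchors + lo_s)


def _window_rate(raster: UnitRaster, lo_ms: float, hi_ms: float) -> float:
    """Mean firing rate (Hz) in [lo_ms, hi_ms) around each stimulus."""
    if raster.stim_times.size == 0:
        return 0.0
    width = (hi_ms - lo_ms) / 1e3
    counts = _window_counts(raster.spike_times, raster.stim_times, lo_ms / 1e3, hi_ms / 1e3)
    return float(counts.mean() / width)


def evoked_rate(
    raster: UnitRaster,
    response_window_ms: tuple[float, float] = (5.0, 25.0),
    baseline_window_ms: tuple[float, float] = (-50.0, 0.0),
) -> float:
    """Evoked AP rate: rate in the post-stimulus response window minus the
    rate 0-50 ms before stimulation, each averaged over stimuli (Hz)."""
    post = _window_rate(raster, *response_window_ms)
    pre = _window_rate(raster, *baseline_window_ms)
    return post - pre


def select_units(
    rasters: list[UnitRaster],
    min_evoked_rate: float = 5.0,
    window_ms: tuple[float, float] = (5.0, 25.0),
) -> tuple[list[UnitRaster], list[UnitRaster]]:
    """Partition units into (kept, excluded) by their mean post-stimulus AP
    rate in the response window of the awake-state raster; the boundary is
    inclusive (exactly the threshold is kept)."""
    kept, excluded = [], []
    for r in rasters:
        rate = _window_rate(r, *window_ms)
        (kept if rate >= min_evoked_rate else excluded).append(r)
    return kept, excluded


def collision_test(
    raster: UnitRaster,
    scan_window_ms: float = 10.0,
    response_window_ms: tuple[float, float] = (3.0, 10.0),
    drop_ratio: float = 0.2,
    min_class_count: int = 20,
) -> dict:
    """Antidromic-spike collision test.

    Stimuli are split by whether a spontaneous spike occurred within
    ``scan_window_ms`` before onset. An antidromic (axonal) response is
    abolished by a preceding spike (the orthodromic and antidromic spikes
    collide), so the unit is flagged antidromic when

        P(response | preceding spike) <= drop_ratio * P(response | none)

    Fewer than ``min_class_count`` stimuli in either class gives verdict
    ``indeterminate``.
    """
    lo, hi = (w / 1e3 for w in response_window_ms)
    scan = scan_window_ms / 1e3
    stim = raster.stim_times
    preceded = _window_counts(raster.spike_times, stim, -scan, 0.0) > 0
    responded = _window_counts(raster.spike_times, stim, lo, hi) > 0
    resp_pre = responded[preceded]
    resp_none = responded[~preceded]
    out = {
        "n_preceded": int(resp_pre.size),
        "n_unpreceded": int(resp_none.size),
        "p_response_preceded": float(resp_pre.mean()) if resp_pre.size else np.nan,
        "p_response_unpreceded": float(resp_none.mean()) if resp_none.size else np.nan,
    }
    if resp_pre.size < min_class_count or resp_none.size < min_class_count:
        out["verdict"] = "indeterminate"
        return out
    p_pre, p_none = out["p_response_preceded"], out["p_response_unpreceded"]
    if p_none == 0:
        out["verdict"] = "indeterminate"  # no response at all: nothing to collide
        return out
    out["verdict"] = "antidromic" if p_pre <= drop_ratio * p_none else "trans-synaptic"
    return out


def relative_fidelity(evoked_drug: float, evoked_ctrl: float) -> float:
    """Evoked rate under drug as a percent of control, floored at 0."""
    if evoked_ctrl <= 0:
        raise ValueError("control evoked rate must be positive")
    return max(100.0 * evoked_drug / evoked_ctrl, 0.0)


def vm_state_histogram(
    vm: Trace,
    epoch: tuple[float, float] | None = None,
    state_boundary_mV: float = -62.5,
    bin_mV: float = 1.0,
) -> dict:
    """Normalised membrane-potential distribution over an epoch, with
    Up-state occupancy (fraction of samples above the boundary) and mean RMP.
    """
    tr = vm if epoch is None else vm.window(*epoch)
    v = tr.values
    if v.size == 0:
        raise ValueError("epoch contains no samples")
    lo = np.floor(v.min() / bin_mV) * bin_mV
    hi = np.ceil(v.max() / bin_mV) * bin_mV
    edges = np.arange(lo, hi + bin_mV, bin_mV)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_mV])
    counts, _ = np.histogram(v, bins=edges)
    density = counts / counts.sum()
    return {
        "edges_mV": edges,
        "density": density,
        "up_occupancy": float(np.mean(v > state_boundary_mV)),
        "mean_mV": float(v.mean()),
    }
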