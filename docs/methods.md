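# Methods

This note records the models the package implements, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate.

## Binomial release model and variance-mean analysis

EPSC amplitudes across sweeps are modelled as a sum of quanta released from
N independent sites, each releasing with probability p_r and contributing a
quantal amplitude q. The mean is I = N p_r q and the variance
sigma² = N q² p_r (1 − p_r), so across conditions that vary p_r the
(I, sigma²) points lie on the parabola sigma² = qI − I²/N. The fit is
linear in (q, 1/N) over the monomials (I, −I²) and is solved by
non-negative least squares, which enforces q ≥ 0 and 1/N ≥ 0 without an
iterative optimiser. When the fitted curvature is zero (all conditions in
the low-p_r regime) only q is identifiable; the estimator reports the
through-origin slope and flags N as unbounded rather than inventing a
number.

Assumptions: uniform q and p_r across sites, no intersite or intrasite
quantal variance in the estimator (the simple parabola carries no quantal
variance correction), no receptor saturation or desensitisation in the
amplitudes supplied. The generator's default cv_q = 0 matches the
estimator's assumption, which makes noiseless recovery exact and keeps the
simulation an internally consistent test of the fit rather than of the
missing correction terms. With cv_q > 0 the generated variance exceeds the
parabola by N p q² cv_q², biasing q̂ upward — that bias is a property of the
simple parabola, not a defect of the generator.

Fitting is unweighted by default; inverse variance-of-variance weighting
(var ≈ 2 sigma⁴/(n−1)) is available but non-default, because with 15 sweeps
per condition the weight estimates are themselves noisy. Parabolas are fit
per cell and group means of the fitted parameters are reported; fitting
pooled points across cells would confound intercell heterogeneity with
within-cell variance.

Percent changes between condition means are computed as
100·(before − after)/before and reported to one decimal.

## Train-based estimation

A 100 Hz, 30-stimulus train depletes the releasable pool faster than it
refills. In the no-replenishment limit the cumulative amplitude after k
stimuli is Nq·(1 − (1 − p_r)^k), so a straight line fit to the late
(steady-state) cumulative points, extrapolated back to stimulus index 0,
converges to Nq; the default steady-state window is stimuli 21–30 and the
depression-magnitude window is stimuli 20–30 of a 30-stimulus train, both
configurable. With replenishment the late points rise by the refilled
quanta per interval and the intercept overestimates Nq; this bias is
inherent to the method and is why the exactness tests use the no-refill
expected-value train. The x-axis is stimulus index, so for a regular train
the index-0 intercept and a time-0 intercept coincide.

A constant-amplitude (non-depressing) train back-extrapolates through the
origin; the estimator flags this as non-estimable instead of reporting
Nq ≈ 0. Recovery from depression is summarised as test-pulse amplitude over
first-pulse amplitude and, with ≥ 3 intervals, fit with
f(t) = 1 − (1 − f0)·exp(−t/tau).

The depletion simulator releases Binomial(available, p_r) quanta per
stimulus and refills the pool toward N between stimuli as
N − (N − n)·exp(−isi/tau_rec). The exponential-refill kinetics are a
modelling choice for the simulator, not an empirical claim; recovery after
strong depression in real terminals can be multi-exponential and
calcium-dependent.

## Hill dose-response and calibration

Fractional block is fit with Y(X) = Max − Max/(1 + (X/EC50)^Hill), bounded
to EC50 > 0, 0 < Max ≤ 100 %, Hill > 0, by nonlinear least squares from a
deterministic multi-start grid (EC50 ∈ {0.1, 0.3, 1, 3} mM ×
Hill ∈ {0.5, 1, 2}, Max started at the largest observed block). The grid
makes convergence behaviour seed-free; the best converged start by SSE
wins. Fitting is done on per-cell blocks averaged within each
concentration (group means); the mean of per-cell fractional blocks is not
the fractional block of mean amplitudes, and the package exposes and tests
both routes. The gas→aqueous calibration is a through-origin line because
solubility at fixed temperature is proportional to partial pressure
(Henry's law); its slope at the standard operating point is
0.72 mM / 3 % = 0.24 mM per gaseous %.

## Capacitance analysis

The exocytic jump ΔC_m is measured as the maximum of block-smoothed C_m in
the 450–500 ms window after the depolarising pulse, minus the mean over a
0.5 s pre-pulse baseline. Everything between pulse end and 450 ms is
excluded because conductance-related artifacts contaminate the capacitance
estimate there; the measurement is therefore invariant to any trace content
strictly inside that interval (tested with an injected artifact transient).
Smoothing is 50-point block averaging (50 ms at the 1 kHz sinusoidal
command rate), with blocks aligned to the pulse end so the measurement
window is exactly one block.

Because endocytosis is already under way in the measurement window, the
measured jump is low by the decay factor 2^(−0.475/half_decay) — about
3.3 % for a ~10 s half-decay. This systematic offset is documented and
bounded (≤ 3.5 %) rather than corrected, since a correction would assume
the decay model that the measurement is supposed to establish.

The endocytic half-decay time is the elapsed time from the C_m peak within
the measurement window until smoothed C_m first falls to baseline + ΔC_m/2,
linearly interpolated between block centers. Measuring from the peak rather
than from the pulse end matters: the measured ΔC_m is itself decayed, so a
pulse-end-referenced crossing time would overshoot the true half-decay by
~4.5 % at these time scales, while the peak-referenced time recovers it to
within 0.1 % on noiseless traces.

Ca²⁺ charge Q_Ca is the trapezoidal integral of inward-current magnitude
over the pulse window (nA·s → pC). The Q_Ca–ΔC_m relationship is reported
per condition as a scatter with an optional saturating fit
ΔC_m = ΔC_max·(1 − exp(−Q_Ca/Q0)); the fit is descriptive only. The
small-charge overlap report restricts conditions to Q_Ca < 3 pC (the regime
where exocytosis tracks Ca²⁺ influx), fits a through-origin line per
condition, and reports the mean absolute difference between condition
predictions over the pooled small charges, relative to the pooled residual
SD. Because the underlying curve is concave, the linear summaries carry a
small curvature residual; the overlap metric is therefore a screening
statistic, not a hypothesis test.

## AP and I-V features

Resting potential is the pre-stimulus mean; amplitude = peak − RMP;
overshoot is the peak above 0 mV; half-width is the width at
RMP + amplitude/2 with linear interpolation on both flanks. The AP
threshold is the voltage at the first sample where dV/dt reaches the
criterion, default 50 V/s — the criterion is a convention, is configurable,
and is recorded in stage outputs. The DAP is the local maximum after fast
repolarisation within 5 ms of the AP peak, minus RMP; the 5 ms window is an
implementation decision surfaced in the function signature. Sub-events
smaller than 20 mV above rest are reported as a no-AP result, not an error.

I–V curves take the signed extremum of largest magnitude per step (inward
negative). Inhibition profiles use magnitudes, 100·(1 − |I_drug|/|I_ctrl|),
with steps excluded when the control magnitude is below 5 % of the largest
control current — percent inhibition of a near-zero denominator is noise.
Exponential decay constants come from least-squares fits seeded by the
segment length; a flat segment returns an infinite-tau flag. Rheobase is
the smallest injected current whose sweep contains a detected spike.

The safety-margin relation between AP overshoot and normalised EPSC is fit
with a continuous piecewise model: a plateau fixed at 1 above a breakpoint
b, a straight decline below it. b is found by deterministic grid search
(candidates are the observed overshoots plus a 401-point uniform grid) with
the decline slope solved in closed form at each candidate; no decline at
all returns a breakpoint censored at the smallest observed overshoot.

## Spike transmission and the in-vivo pipeline

Transmission fidelity matches each presynaptic AP to at most one
postsynaptic AP in a latency window after it (default 0.2–3.0 ms, the
monosynaptic delay scale at a calyceal synapse), greedily in time with each
postsynaptic AP used once. The window must be shorter than the presynaptic
inter-spike interval or matching is ambiguous and an error is raised. The
matching criterion is a package decision: experimental descriptions of
"following" rarely pin down a window, so it is an explicit parameter.

PSTHs are stimulus-aligned counts per bin (default 5 ms), with rates
counts/(n_stim·bin). Unit inclusion keeps units whose mean rate in the
5–25 ms post-stimulus window is at least 5 Hz, boundary inclusive. The
evoked rate is the 5–25 ms rate minus the rate over the 50 ms before the
stimulus, each averaged over stimuli — an unbiased estimate of
p_evoked/0.020 s on top of any stationary background. Relative fidelity is
the evoked rate under drug as a percent of control; per-unit and
group-mean averaging of such ratios differ, and both routes are exposed.

The collision test splits stimuli by whether a spontaneous spike occurred
in a scan window (default 10 ms) before onset and compares response
probabilities in the 3–10 ms antidromic latency band. An antidromic spike
travelling up the axon is annihilated by a just-fired orthodromic spike, so
a preceding spontaneous spike abolishes the response; a trans-synaptic
response is indifferent to it. The unit is flagged antidromic when
P(response | preceded) ≤ 0.2·P(response | unpreceded). Fewer than 20
stimuli in either class returns "indeterminate" rather than a guess —
at spontaneous rates of a few Hz the preceded class is a small fraction of
stimuli, so classification needs on the order of a thousand stimuli.

Membrane-potential state analysis histograms a 30 s epoch in 1 mV bins and
reports Up-state occupancy as the fraction of samples above a boundary,
default −62.5 mV — the midpoint of typical Down (≈ −70 mV) and Up
(≈ −55 mV) states.

## Synthetic data: what it emulates and what it does not

Every generator draws from one root seed with child streams spawned per
call, so a fixed seed and call order reproduce outputs byte-for-byte.

The generators reproduce the statistical structure each estimator assumes:
binomial quantal sums (with optional truncated-Gaussian intrasite
variability, resampled at zero because amplitudes are magnitudes),
depletion trains with exponential refill, Hill-shaped block with Gaussian
noise clipped to [0, 100] %, capacitance jumps with exact half-life
parameterised decay, rectangular Ca²⁺ pulses with closed-form charge,
regular presynaptic trains with independent Bernoulli transmission,
homogeneous-Poisson unit backgrounds with at most one evoked spike per
stimulus, and exponential-dwell two-state membrane potentials.

They deliberately do not emulate: electrode/access-resistance artifacts,
receptor saturation and desensitisation, intersite p_r dispersion,
facilitation, multi-exponential or calcium-dependent pool recovery,
bursting or refractory structure in background spiking, or conductance-based
AP waveforms. Passing recovery tests therefore show that the estimators
invert the models they assume at realistic protocol scales and noise — not
that those models capture every feature of real recordings.

Default simulation scales mirror standard protocols: 15 sweeps per
variance-mean condition across four release probabilities spanning
0.1–0.9; 30-stimulus 100 Hz trains; 8 cells per concentration on a
5-concentration dose grid with 2 % block noise; 200-AP paired trains;
400–1000 photostimuli per unit at 0.2–2 Hz with ~7 Hz spontaneous rates.
Monte-Carlo checks use 30–200 replicate seeds, chosen so medians and means
are stable at the tolerances tested.

## Numerical choices and degenerate inputs

- Non-negative least squares for the parabola (no sign flips from noise);
  curvature ≤ 0 reports unbounded N instead of a negative site count.
- All nonlinear fits (Hill, recovery, decay, saturating release) use
  bounded `scipy.optimize.curve_fit` with deterministic starts; the Hill
  fit multi-starts from a fixed grid and raises a diagnosable error if no
  start converges (e.g. all-zero blocks, where Max is unidentifiable).
- Trapezoidal integration for charge; block means for capacitance
  smoothing; linear interpolation for half-width, half-decay and threshold
  crossings.
- Zero baselines (percent change, fractional block, p_r denominators) raise
  rather than returning infinities; p_r > 1 is returned with a warning flag
  since it is diagnostic of a bad pool estimate rather than impossible
  arithmetic.
- Event series are sorted and de-duplicated at 0.1 ms; traces validate
  strictly increasing timestamps and declare units.

## Known limitations

- The variance-mean estimator ignores quantal variance and p_r dispersion;
  with heterogeneous sites N̂ is an effective (dispersion-weighted) site
  count.
- Back-extrapolated Nq overestimates the pool whenever replenishment is
  non-negligible during the steady state; the package reports the estimate
  as defined, without a refill correction.
- The small-charge overlap report summarises curves linearly below
  threshold and inherits curvature residuals.
- The collision test assumes stationary spontaneous activity; strong
  stimulus-locked inhibition just before the response window would bias the
  preceded-class response probability.
- Descriptive statistics only: the package reports means ± SEM and percent
  changes, and leaves inferential testing to the caller.
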