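# Methods

## Scope and model of the data

`shiftsense` treats one officer-shift as three synchronized records keyed by
UNIX time: a wrist-sensor session (electrodermal activity and skin
temperature at 4 Hz, 3-axis acceleration at 32 Hz, blood volume pulse at
64 Hz, irregular interbeat intervals), a computer-aided-dispatch (CAD) log of
call lifecycles, and an automated-vehicle-locator (AVL) ping track. The
pipeline reduces these to a table of 19 metrics on nonoverlapping 20-second
windows, fuses in dispatch phase and location, and models trajectories of a
chosen metric across officers with a linear mixed model.

## Windowed feature extraction

**Electrodermal decomposition.** The 4 Hz skin-conductance signal is split
into a tonic *baseline* (0–0.04 Hz) by a third-order Savitzky–Golay filter
and a phasic *bandpass* fluctuation signal (0.04–0.4 Hz) by a second
third-order Savitzky–Golay filter applied to the baseline-removed residual.
The nominal 100- and 10-point windows are realized as 101 and 11 points: a
centered polynomial filter needs odd length, and these are the nearest valid
sizes (empirical −3 dB cutoffs ≈ 0.05 and 0.5 Hz at 4 Hz sampling; a 0.2 Hz
probe sine reaches the bandpass signal with gain 0.93 and leaks into the
baseline with gain 0.04). Edges use reflect padding; the first/last
half-window of the baseline filter is retained, not trimmed, and downstream
edge-sensitive metrics handle their own coverage rules.

**Windowed electrodermal metrics** (per 20-s window, 80 samples):

* mean baseline level; least-squares line slope of the baseline over the
  window, and over ±60 s around the window midpoint (the 120-s slope is
  missing when edge truncation leaves under 50% of that span);
* RMS of the bandpass signal;
* difference and z-score normalizations of the level and the RMS against the
  population of the 60 windows spanning 20 min 20 s to 20 s before the
  window's time stamp (i.e. windows k−61 … k−2). The z score uses the
  sample (n−1) standard deviation; a zero-variance population leaves the z
  metric missing. The first 61 windows of a session have no full population
  and report all four normalized metrics missing;
* peak counts and mean peak heights at two thresholds (0.15 and 0.02 µS):
  local maxima of the bandpass signal within the window, height measured as
  the signal value at the maximum (not prominence, since the thresholds are
  absolute), maxima closer than 1 s pruned keeping the larger (ties: the
  earlier). Zero-peak windows report a missing mean height — the mean of an
  empty set — rather than 0.

**Activity.** The three acceleration axes are collapsed to the Euclidean
norm √(x²+y²+z²), band-passed to 0.1–7 Hz with a design-order-5 Butterworth
applied forward–backward (zero phase, effective order 10), and summed as
|activity| over 1-s epochs; the windowed metric is the mean of the 20
epoch counts. The norm rather than a signed radicand is used because a
magnitude is what an activity count measures.

**Quality flags.** The vendor's proprietary per-5-s data-quality algorithm
is replaced by a pluggable surrogate: an interval is bad when conductance
leaves [0.01, 100] µS, jumps more than 5 µS between consecutive samples, or
skin temperature leaves [20, 45] °C. The windowed bad-data value is the sum
of the window's four ±1 flags, hence {−4, −2, 0, 2, 4}. Thresholds live in
`FeatureConfig`.

**Time.** Window k's time stamp is `session_start + 20k`. Elapsed time from
midnight is relative to the most recent local midnight with a configurable
timezone offset, default UTC; shifts routinely span midnight, so the metric
wraps below 20 inside the crossing window.

## Dispatch events and fusion

Call lifecycles become a 1 Hz assignment stream: 0 unassigned, 0.5 canceled
call, 1.0 dispatch→arrive-1, 2.0 arrive-1 until the next lifecycle event,
2.5 arrive-2→transport when arrive-2 precedes transport, 3.0
transport→cleared. Two conventions the source data leave open: a canceled
call (which has no cleared time) holds its 0.5 value for a configurable 300 s
after dispatch, and an arrive-2 with no transport keeps 2.0 until clearance.
The per-window event code is the mode of the 20 per-second values with ties
broken toward the larger value — deterministic, and biased toward the deeper
call phase. Location linkage takes the ping nearest the window midpoint
within 30 s, matching the slowest ping cadence of the vehicle feed; fusion is
a strict left join that never changes the row count, and the `allocated`
flag is true when call-assigned seconds hold a majority of the window.

## Interbeat-interval quality

A beat at offset o with interval d covers [o−d, o]. "Valid data" is
gap-free tiling within a 0.25 s tolerance; gaps also open at the session
edges, so valid-segment lengths plus gap lengths tile the session exactly.
Reported: longest valid segment, gap mean and SD (population SD, so a lone
gap has SD 0), and a per-20-s rating mirroring the electrodermal bad-data
scale: each 5-s interval is good when beats cover ≥ 80% of it. Both the
tolerance and the coverage fraction are arguments. Heart-rate-variability
metrics themselves are out of scope — quality assessment is the gate that
precedes them.

## Mixed-model trajectory analysis

Level-1 observations (windows) nest in level-2 officers:

    Y_it = β0 + u0i + β1·time + u1i·time + β2·Intx_it + β3·(Intx·time)_it + e_it

with time coded 0 at each shift start, (u0i, u1i) ~ N(0, G), and e_it
independent, AR(1), or banded-Toeplitz within an officer. Estimation is by
ML (for model comparison; mixing REML fits into a comparison is rejected) or
REML (for reported estimates). The likelihood is profiled over β and
evaluated per officer: residual correlation is whitened away (closed form
for AR(1), banded Cholesky for Toeplitz), then the random-effect term is
handled with the Woodbury identity, so cost is linear in windows.
G is parameterized by its log-Cholesky factor, the error variance on the log
scale and correlations through tanh; optimization is L-BFGS-B with a
Nelder–Mead polish, infeasible points taking a large finite penalty.

Small-sample inference: with independent errors the fixed-effect covariance
gets the Kenward–Roger adjustment for covariance structures linear in the
variance parameters (the second-derivative term of V vanishes), using the
expected REML information, and degrees of freedom come from a
Satterthwaite-type formula on the variance-parameter covariance; the
adjustment is floored so it never shrinks a variance. For AR(1)/Toeplitz
errors V is nonlinear in the correlation parameter and the module falls back
to Satterthwaite df via numerical derivatives of the profiled likelihood.
Every fit records the method used (`kenward-roger`, `satterthwaite`, or
exact `residual` df for the no-random-effects case). In the balanced designs
the simulation harness produces, the Kenward–Roger inflation term is exactly
zero because GLS coincides with OLS; the df correction carries the
small-sample control, and a cross-check against lmerTest's Satterthwaite
implementation reproduces its estimates, standard errors and df to print
precision. Rows missing the outcome or any predictor are dropped listwise
with a logged count. Per-officer best linear unbiased predictors of
(u0i, u1i) are exposed on every fit.

`phase_contrast` reports per-class descriptive mean/SD of a windowed metric
plus a model-based contrast (class dummies as fixed effects, random officer
intercept when two or more officers are present).

## The synthetic-shift generator

No real officer recordings are distributable, so the generator is the
package's study population. It emulates:

* electrodermal activity as tonic level 1.0 µS with 0.05 µS/h drift, plus a
  train of skin-conductance responses — unit-peak bi-exponential kernels
  (rise 0.75 s, decay 4 s), amplitudes uniform on 0.2–0.8 µS, a 2 s
  refractory separation — arriving at 0.5/min off-call, 1/min during
  low-stress calls and 5/min during high-stress calls, plus 0.01 µS Gaussian
  sensor noise; conductance is clipped at 0.001 µS because it is a positive
  quantity. These are conventional magnitudes for wrist electrodermal
  recordings, not calibrated to any deposited dataset (none exists);
* skin temperature around 33 °C with a slow swing; acceleration as gravity
  plus noise, spontaneous movement bouts (4/h, ~1 min) and vehicle
  vibration while en route; a schematic blood-volume-pulse waveform;
* interbeat intervals from a stress-modulated heart period (0.85 s at rest,
  0.12 s shorter during high-stress calls, 0.02 s beat jitter) with random
  contiguous deletions (2 gaps/h, 10–60 s) emulating optical-sensor dropout;
* a dispatch log from explicit call specifications and a vehicle track that
  pings every 5 s en route and every 30 s stationary, on planar coordinates
  (location is used only for linkage, so no geodesy).

Every injected schedule — SCR times and amplitudes, realized interbeat gaps,
movement spans, stress spans — is retained as ground truth, and all
randomness flows from one integer seed through independent per-channel
substreams, so outputs are byte-identical for a fixed configuration. What
the generator does **not** emulate: motion artifacts in the electrodermal
channel, electrode drying, physiologic waveform morphology, road networks,
or officer behavior feedback. Tests passing on this population therefore
demonstrate the pipeline's correctness and sensitivity under clean,
known-truth conditions, not robustness to real-world artifact.

## Numerical and testing choices

* Streams cover [start, start + duration): the last sample sits at
  duration − 1/rate, so a 12-h, 4 Hz stream has exactly 172,800 samples.
* Windowed metric oracles in the test suite are naive per-window loops
  (agreement to 1e-9); peak detection is checked against exhaustive
  enumeration with greedy pruning; window quality against grid-based
  interval intersection; the mixed model against closed-form OLS and the
  statsmodels mixed-model implementation.
* The Monte-Carlo recovery study runs 100 replicates of 3 officers × 2160
  windows (a full 12-h shift at 20 s) at β = (0.3, 0, 0.6, 0), σ = 0.3,
  var(u0) = 0.01; shorter series were observed to truncate the
  between-officer variance at zero noticeably more often, an artifact of
  shrinking the series, so the study runs at the full per-shift length.
* File writers format floats to six decimals; round trips are exact to 1e-6
  by contract, and readers validate rather than coerce.

## Known limitations

* The bad-data surrogate is a range-and-jump heuristic, not the vendor's
  algorithm; its flags agree with it only in the obvious failure modes.
* Kenward–Roger inflation is implemented for independent level-1 errors;
  correlated structures get Satterthwaite df only.
* The event-code mode and the canceled-call hold are conventions where the
  dispatch format is silent; both are parameters.
* One officer per session; multi-officer datasets are lists of sessions,
  matching the two-level structure of the model.
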