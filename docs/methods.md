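# Methods

`mothnav` models the sensory-motor chain by which a male moth (or a robot
carrying a moth antenna) tracks a pheromone plume: a single command neuron
whose multiphasic On / inhibitory / Off response encodes presence and recent
loss of the stimulus, an online rule that converts that response into surge
and casting commands, and a search-theoretic account of how good the casting
strategies can possibly be.  This note records the model equations, the
calibrated parameters and why they have the values they have, what the
synthetic components do and do not emulate, and the numerical conventions.

## Command neuron

Single compartment, five currents:

    C dV/dt = -I_Na - I_K - I_leak - I_Ca - I_SK + I_drive

* `I_Na = g_Na m_inf(V)^3 h (V - E_Na)`, `I_K = g_K n^4 (V - E_K)` with
  Wang-Buzsaki fast-spiking kinetics (instantaneous activation `m`,
  temperature factor folded into the `h`/`n` rates).
* `I_Ca = g_Ca s_inf(V)^2 (V - E_Ca)`, `s_inf(V) = 1/(1+exp(-(V+25)/5))` —
  a high-voltage-activated current that admits Ca2+ essentially only during
  spikes.
* Calcium pool: `dCa/dt = -k_Ca I_Ca - (Ca - Ca_rest)/tau_Ca`.
* `I_SK = g_SK * Ca^2/(Ca^2 + K_SK^2) * (V - E_K)` — SK activation is an
  instantaneous Hill function of Ca2+.

Spikes are upward crossings of 0 mV with a 1 ms refractory period.
Integration is fourth-order Runge-Kutta, step 0.01 ms for the response
experiments and 0.05 ms in the closed-loop simulator (halving the step moves
every spike time by far less than 0.1 ms; a convergence test asserts this).
A non-finite state aborts with the name of the first bad variable and the
time.

The published description of this cell type fixes the current set and the
qualitative mechanism but not the constants, so the free parameters
(`g_Ca = 0.1 uS`, `g_SK = 0.5 uS`, `tau_Ca = 400 ms`, `k_Ca = 0.0016
uM/(nA ms)`, `K_SK = 0.4 uM`, drive gain) were calibrated once against the
measured response laws and then frozen as the dataclass defaults:

* On duration tracks stimulus duration (slope ~1): during the stimulus the
  ORN plateau drive out-competes the saturated SK current; the burst ends
  when the drive collapses at stimulus offset.
* Inhibitory phase ~400 ms, independent of stimulus duration: Ca2+
  equilibrates within the shortest stimulus (hence `tau_Ca` well below the
  stimulus range is impossible, and `tau_Ca` far above it would make I grow
  with duration; 400 ms balances both against the Hill steepness `n = 2`).
* Off discharge: the slow component of the ORN decay rides above rheobase
  for seconds while SK relaxes; no separate Off current exists.
* Blocking SK (`scale_sk`) removes the inhibitory phase and turns the
  response monophasic.  The block factor maps `[0, 1]` onto the conductance
  sweep `[0.05, 0.5] uS` used in the antagonist-washout comparison, with
  factor 0 meaning complete block (`g_SK = 0`).

## ORN population input

Per-ORN rate `lambda(t)` (42 ORNs): baseline 12 Hz, and per pulse a
latency-shifted triphasic response — exponential rise (tau 20 ms) to a peak
1.6x the adapted plateau (adaptation tau 120 ms), then a biphasic decay
(fast tau 15 ms carrying 65% of the amplitude, slow tau 4 s carrying 35%).
The abrupt fast decay is what gives the burst a sharp end (required by the
online detector); the slow tail is what sustains the Off for seconds.

Dose enters twice: a saturating Hill law for amplitude (`amp_max = 75 Hz`,
`k = 0.05 ng`, exponent 0.35 — logarithmic-like sensitivity over the
0.001-10 ng range), and a latency shift of the response onset.  The latency
parameters (`lat0 = 206.6 ms`, slope `-10.59 ms/decade`) are NOT the printed
behavioural law: the downstream neuron adds its own dose-dependent
integration delay, and `calibrate_dose_law` fits the model-internal law so
that the *measured* On latency reproduces -16 ms x log10(dose) + 230 ms.
The shipped defaults are the output of that calibration (measured slope
-14.8 ms/decade, 230.4 ms at 1 ng).

A later pulse truncates the decay tails of earlier pulses (receptor and
adaptation state restart).  Without this reset, slow tails superpose across
pulse trains, the drive floor rises, and the inter-pulse inhibitory phase
disappears — contradicting the observed pulse tracking.  With it, the Off
between pulses is truncated by the next On, which is precisely what produces
the linear Off-duration-versus-air-gap law (slope ~1.0, Off absent at 300 ms
gaps where the next response begins before SK has released the cell).

Population spiking is non-homogeneous Poisson.  `sample_population` draws
per-ORN trains by thinning against the rate ceiling (300 Hz).  The pooled
fast path (`sample_population_counts`) uses the superposition property: the
sum of 42 independent Poisson processes is Poisson with rate `42 lambda(t)`,
drawn directly as 1-ms bin counts (bin means < 0.013, so the discretization
is negligible; a KS test against the thinning sampler asserts agreement).
Spikes convert to current through a causal exponential kernel
(0.04 nA x exp(-t/15 ms), one shared kernel for the population).

The generator emulates rate dynamics and Poisson variability only: no
receptor-binding kinetics, no ORN heterogeneity, no electroantennogram
waveform.  Tests passing on this input validate the neuron's firing-pattern
logic, not any claim about real receptor transduction.

## Phase segmentation and spike statistics

Instantaneous rate: Gaussian kernel, sd 50 ms for On detection (low
baseline variance), 20 ms where boundaries are refined.  On onset = first
excursion above `max(baseline + 4 sd, 15 Hz, 1.3 x baseline max)` sustained
for 30 ms and peaking at 1.5x threshold, refined to the first spike.  The
burst then extends while inter-spike gaps stay below 150 ms; the first
longer gap ends the On and is the inhibitory-phase candidate (a rate
threshold cannot resolve a few-hundred-ms silence at these low spontaneous
rates, and the model's late-plateau firing has gaps up to ~110 ms, so the
150 ms bound separates the two cleanly).  The I phase must begin within
800 ms of the stimulus-locked response offset — later silences belong to the
decaying tail of a monophasic response, not to an inhibitory phase.  The Off
runs from the end of the I gap until the rate returns to baseline for 200 ms
(or until the next pulse's On in trains).

Precision/reliability: all trial pairs are greedily matched one-to-one
within 25 ms; sigma = sd of matched offsets / sqrt(2) (so it estimates the
per-trial jitter rather than the jitter of a difference — an ensemble
jittered with sd 3 ms reports sigma ~3 ms), rho = pooled unmatched fraction.
This pairwise matcher is a deliberate simplification of the published
variational spike-train synchrony estimator; it is validated against
constructions with known ground truth, and no comparison with the recorded
neurons' absolute sigma/rho values is attempted.  Surrogates for the null
anchor the first spike and permute the inter-spike intervals, preserving
each trial's ISI multiset while destroying within-trial timing; original
and surrogate per-pair values are compared by Mann-Whitney.

PSTH: 100 ms windows advancing 50 ms.  Autocorrelation: binned counts,
normalized to 1 at lag zero.  ROC: the detection statistic for k neurons is
the count of reference-neuron spikes with coincident spikes (within the
window) in every other neuron; the curve is swept over the integer count
threshold from high to low and integrated by trapezoid.

## Online detection and policies

The surge trigger is the On-burst-then-inhibition signature: three
consecutive interspike intervals < 70 ms arm the detector, and the event
fires at (last burst spike + 350 ms) provided no spike intervenes — the
earliest moment the criterion is provably satisfied, so the detector is
causal.  Any intervening spike (ISI in [70, 350) ms) restarts tracking.
With two neurons, surge requires coincident events (within 300 ms, emitted
at the later of the pair); coincidence can only remove events, never add.

Policies run at constant speed 5.6 cm/s.  One-step: surge upwind for 5 s
after each event, otherwise spiral.  Two-step: surge 5 s, crosswind zigzag
19 s, then spiral.  Zigzag legs start at 0.05 m and double every reversal —
the 19 s window then spans four full legs and ends with the agent back near
the casting origin.  The simulator's spiral is Archimedean (initial radius
0.2 m ~ a robot turning circle, pitch 0.3 m/turn), started in a random
direction each trial (the robot's heading at cast onset was arbitrary); the
theory module uses the logarithmic spiral.  A fresh event preempts any
casting phase and restarts the surge timer.

## Arena and plume

Arena 2.5 m x 4 m (crosswind x wind axis), start (0, 0), source (0, 2),
wind toward -y at 0.9 m/s, goal radius 0.2 m, kinematic step 100 ms, sensing
grid 1 ms.  Wall contact slides the agent along the wall (clamping).  The
trial timeout is 300 s: successful searches take ~1-4 minutes of path at
5.6 cm/s, and the published trial count (163) is only consistent with
trials of a few minutes, not tens.

The plume process is the central modelling liberty — the original robot
sensed a real plume, whose intermittency statistics are unknown.  The
simulator uses a patch-encounter rate field

    nu(x, y) = nu0 * min(sqrt(2 m / dy), 4) * exp(-((x - xc(t, dy)) / (w sqrt(dy)))^2)

for downwind distance `dy = y_src - y + 0.1 m > 0` (the 0.1 m virtual
origin gives the corridor a small finite width at the source itself — a
real plume is not a zero-width parabola tip) and zero upwind, with
`nu0 = 0.25 /s` (patch encounters a few seconds apart at the start) and
`w = 0.12 m/sqrt(m)`, so the 90%-of-detections contour is parabolic.  The
`sqrt(1/dy)` factor is flux conservation: the same patch flux crosses every
downwind section, so the peak rate rises as the corridor narrows.  The
centerline `xc` meanders crosswind as an Ornstein-Uhlenbeck process (sd
0.3 m at the start distance, correlation time 10 s) scaled by
`sqrt(dy / 2 m)` so the plume stays anchored at the source.  Each encounter
delivers a 200 ms, 1 ng patch to the ORN model; overlapping encounters
extend the contact.  A separate sensor-noise channel produces rare spurious
patches (0.004 /s, 0.001 ng — at the steep part of the detection curve)
independent of position and of the pheromone; these model the
electroantennogram noise blips that caused the robot's false alarms, and
their per-neuron detection probability of roughly one half is what
two-neuron coincidence gating filters quadratically.

Because every plume constant above is invented, all plume-dependent results
are held to ordinal standards only (intact beats blocked; coincidence
reduces false events; two-step at least matches one-step), never to the
published percentages or metre values.

Track angles are movement vectors relative to upwind, computed on 5 s
trajectory segments and subsampled to at most 300 pooled vectors per
condition — the granularity of behavioural track analyses; at the
simulator's native 100 ms resolution any hair of anisotropy in tens of
thousands of vectors is statistically "significant", which would make the
uniformity comparison meaningless.  The Rayleigh test uses Zar's
approximation (cross-checked against an independent implementation).

## Search theory

Setting: target at distance d, detection exactly and only where the casting
path crosses the target's downwind centerline half-line, then a straight
surge along the centerline to the target.  The competitive ratio is the
worst case over target placements of (casting path + surge)/d.

Zigzag-surge (target not downwind): the casting cost to reach the
projection offset `|d cos(phi)|` is the classical geometric linear-search
(cow-path) cost — worst case `(1 + 2 m^2/(m-1)) = 9` at doubling factor
m = 2 in the infinitesimal-initial-leg limit, which the implementation
obtains by simulating the leg schedule and extrapolating over decreasing
initial legs with a convergence check.  Adding the orthogonal surge
`d sin(phi)` and maximizing over phi gives `max 9 cos + sin = sqrt(82) =
9.0554`, attained with the target ~6.3 degrees off the search line just
beyond a reversal point.

Spiral-surge (no direction information): logarithmic spiral `r = e^{b
theta}` in the vanishing-inner-radius limit.  The ratio is scale-invariant
(scaling the target by `e^{2 pi b}` maps the spiral onto itself), and the
worst case over targets lies on the closure of two discontinuity families:
(A) the target exactly on the spiral, so that detection just misses the
target and defers to the next crossing of its centerline; and (B) the
centerline vertically tangent to a spiral turn, so that the near-crossing
pair just vanishes.  Both families are one-dimensional and are maximized by
dense scan plus local refinement; a coarse two-dimensional grid over target
placements confirms no other family matters.  Minimizing the sup over the
growth rate (Brent) gives r = 22.513 at b* = 0.1137.  Convergence is
declared when doubling the angular resolution changes r by < 5e-4;
otherwise the result is flagged non-converged.  The surge leg from the
detection point p to the target t lies along the centerline, so "surge along
the centerline" and "straight p to t" coincide.

## Problem sizes and seeds

Response experiments use 10 runs per condition at integration step 0.01 ms
(about 30 s of simulated time per run).  Navigation batches run at 0.05 ms
with the chunked reduced-fidelity pipeline: 30 trials per arm for the
SK-block comparison (the success difference is large), and 100 matched-seed
trials per arm with an uncensored 20-minute timeout for the casting-strategy
comparison, whose search-distance effect (~20% of the median, heavily
overlapping distributions) needs that sample for a reliably powered
rank test — comparable to the published 99-trial design.  Every
generator takes an explicit seed; batch drivers derive per-trial seeds from
the master seed, and a trial is bit-reproducible from its seed alone.

## Known limitations

* All constants of the biophysics are calibrated to reproduce the printed
  response laws, not fitted to raw recordings; the model is a mechanism
  demonstration, not a parameter estimate.
* The plume is a statistical caricature (Poisson patches, Gaussian
  crosswind profile, OU meander); no fluid dynamics, no vertical structure,
  no concentration dynamics within a patch.
* The two-neuron mode perturbs only `g_SK` and `tau_Ca` (20% CV), mirroring
  the stated heterogeneity, and shares the kernel and rate model.
* The pairwise sigma/rho estimator is biased upward when unrelated
  background spikes fall inside the matching window; validation uses clean
  locked ensembles.
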