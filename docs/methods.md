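# Methods

## Model

The network is a continuous-time leaky firing-rate RNN,

    tau dr/dt = -r + f(W_rec r + W_in u + b + sqrt(2 tau sigma_rec^2) xi),

with Softplus nonlinearity f(x) = log(1 + e^x), neuronal time constant
tau = 100 ms, recurrent noise strength sigma_rec = 0.05 (xi is unit-variance
white noise per unit), and a logistic readout z = g(W_out r),
g(x) = 1/(1 + e^-x).  The dynamics are integrated by forward Euler with
dt = 20 ms (alpha = dt/tau = 0.2):

    r_t = (1 - alpha) r_{t-1} + alpha f(q_t),
    q_t = W_rec r_{t-1} + W_in u_t + b + sigma_rec sqrt(2/alpha) eps_t,

with eps_t a fresh standard-normal draw per unit and step.  The
sqrt(2/alpha) factor is the discrete counterpart of the sqrt(2 tau
sigma_rec^2) continuous scaling: the noise variance accumulated over a fixed
wall-clock interval is invariant to the choice of dt (verified by simulation
in the test suite).  Because the update is a convex combination of the
previous state and a positive function value, activity stays nonnegative.
Noise enters inside f, exactly as in the dynamics equation, not added to the
state.  The initial state is r_0 = 0 (configurable).

Initialization: W_rec is a random orthogonal matrix (scipy's `ortho_group`),
W_in has i.i.d. N(0, 1)/sqrt(n_in) entries, W_out is Glorot-uniform on
+-sqrt(6/(n_rec + n_out)), and the background input b starts at zero and is
trainable.  Weights are unconstrained in sign.

## Tasks

Trials are (time x trials x channels) tensors.  Input channels: one binary
fixation unit (1 while fixation is required, 0 after the go signal), a ring
of direction-tuned stimulus units (8 by default; 360 for fine-grained
simulations) with preferred directions uniformly spaced on [0, 2pi), and a
one-hot task-rule block.  Epochs follow the primate protocol: 1 s fixation,
0.5 s cue, a delay (1.5 or 3 s fixed, or drawn uniformly from 0-3 s in 0.1 s
increments in variable-delay training), and a 0.5 s response epoch.  Cue
locations are the eight angles 0, 45, ..., 315 degrees.  The ODRD variant
inserts a to-be-ignored distractor strictly inside the delay; "anti" tasks
require the response opposite the cue.  The default six-task battery is
ODR, ODRD, their anti counterparts, and two zero-delay control tasks; single-
task registries are used for the scaled-down experiments.

Design choices where the protocol leaves freedom:

- **Stimulus profile.**  Von Mises activation with full width at half
  maximum 71 deg, placing about one third of the peak drive on adjacent
  units of the 8-ring; a graded code keeps the 360-unit variant meaningful.
  One-hot encoding is available via `tuning_width=0`.  Peak drive 1.0.
- **Input noise.**  Additive Gaussian, sd 0.01 per channel and timestep.
- **Targets.**  Fixation output 1 while fixation is required, 0 after; ring
  targets hold a 0.05 baseline outside the response epoch and a bump (same
  von Mises profile, peak 1) centered on the required direction during it.
- **Loss mask.**  Unit weight everywhere, x5 during the response epoch, and
  zero during the first 100 ms after the go signal (a grace period for the
  finite rise time of the readout).

## Training

Masked mean squared error L = sum(mask (z - y)^2) / sum(mask), minimized
with Adam (eta = 0.001, beta1 = 0.9, beta2 = 0.999, eps = 1e-8) over
minibatches of 64 trials with tasks interleaved (stratified when the
registry has several).  Gradients flow through the full unrolled trial (no
truncation; trials are at most a few hundred steps) and are clipped at
global norm 1.0 (rarely active in practice: about 3% of updates early in
training).  The reverse pass is written out in closed form and verified
against central finite differences to ~1e-9 in the test suite; the unrolled
pass runs in single precision (float32 gradients match float64 to ~1e-6
relative, far below the recurrent-noise floor), while the master weights and
Adam moments stay in double precision.

Evaluation draws fresh seeded trials, simulates them with the recurrent
noise kept at its training value, decodes the response with the
population-vector method, and scores a trial correct only if the fixation
output stayed above 0.5 at every bin while the fixation input was on and the
endpoint fell within 36 degrees (inclusive) of the required direction.
Performance stages: early (< 35% correct), mid-trained [35, 65), mature
[65, 95), fully trained (>= 95%); the printed band edges overlap at 65 and
95, resolved here as half-open intervals.  Training halts at the fully
trained stage or after `max_steps` updates.  Every update and evaluation
draws from a substream keyed by (seed, step index), so a run can be resumed
from a checkpoint bit-exactly.

## Behavioral analyses

The endpoint of each trial is the population vector of the ring outputs
averaged over the final 200 ms of the response epoch (a window average is
more robust to transients than the final bin; the window is configurable).
Signed deviations (endpoint minus required direction, wrapped to
(-180, 180]) are histogrammed in 9-degree bins centered on multiples of 9.

## Unit-level analyses

Units with persistent activity ("delay units") are those whose per-trial
mean delay rate exceeds the fixation-period rate with Welch's t-test at
p < 0.05 (one-sided elevation required; all two-sample tests in the package
are Welch, with degrees of freedom reported).  Tuning curves are mean
delay-window rates per cue location; each unit's curve is rotated so its
preferred (argmax) location sits at the center index before averaging across
units.

**Rate-behavior correlation.**  For correct trials of each cue location, a
trial's rate deviation is its delay-window mean rate minus the median across
same-cue trials (window: last 1 s of the delay); its saccade deviation is
the absolute deviation of the endpoint from the per-cue median endpoint,
signed positive when the endpoint lies closer to the unit's preferred
location than the median endpoint does, negative when farther, with exact
ties excluded.  Medians of endpoints are taken on deviations from the cue
(already wrapped), not on raw angles.  Pearson r is computed per unit and
location (cells with fewer than `min_trials` usable trials or zero variance
are undefined), rotated to preferred-at-center, averaged into a population
curve, and summarized by the grand mean with a one-sample t-test against
zero.  A drifting memory trace predicts the "M" shape: positive r on the
tuning-curve flanks, none at the peak and the opposite location.

**Fano factor.**  Variance (n-1 denominator) over mean of per-trial
delay-window rates across 16 correct trials per location, per unit, rotated
and averaged the same way.  The delay window is a parameter: the protocol
names both the entire delay and its last 1 s; the default is the last 1 s,
matching the correlation analysis.  Cells with mean below 1e-6 are excluded
(counted, not silently dropped), as are baselines below 1e-6 in normalized
rates.

**Correct vs error contrast.**  Each delay unit contributes its mean
last-1 s delay rate over correct trials at its preferred location and,
separately, over error trials there; observations are pooled across networks
and compared with Welch's t-test.

**Weight structure.**  Recurrent rows/columns are sorted by preferred
location; the diagonality statistic is the mean recurrent weight over
ordered unit pairs with preferred locations within 45 degrees (circular,
self-pairs excluded) minus the mean over pairs at least 135 degrees apart.
Positive values reproduce the connectivity footprint of bump-attractor
models.

## Synthetic ground truth

`drifting_bump_surrogate` emulates an idealized bump attractor: a bump of
activity centered on the cue performs a Gaussian random walk through the
delay, each unit's rate is its circular tuning curve evaluated at the bump
position (plus small observation noise), and the behavioral endpoint is the
bump position at the go signal.  It reproduces the M-shaped correlation and
Fano curves by construction, and freezing the drift removes both — the
ablation the analysis tests rely on.  What it does not emulate: learned
heterogeneous tuning, output decoding through a readout layer, fixation
behavior, or any trial-to-trial correlation structure beyond the single
drifting mode; passing these tests validates the analysis chain, not the
trained networks themselves.

## Problem sizes

The scaled-down experiment used throughout the tests and the acceptance
script trains 128-unit networks on single-task ODR with a fixed 1.5 s delay
(the full-scale protocol uses 256 units, six tasks and 30-network
ensembles; ensemble size and unit count are configurable).  Analyses use
balanced recordings of 40 trials per cue location, 16 correct trials per
location for the Fano factor, and an evaluation set of 500 fresh trials.

## Known limitations

- Multi-task training demonstrably eases acquisition of the delayed-response
  task; single-task fixed-delay training from scratch shows long loss
  plateaus before the memory solution emerges, and individual seeds differ
  several-fold in the number of updates they need (in a ten-seed run, eight
  networks reached the fully trained stage within 600-2100 updates and two
  stalled below it at the 3000-update budget).
- The magnitudes of the variability statistics are scale-dependent.  The
  scaled-down single-task networks are very clean: their delay-period Fano
  factor comes out around 0.003-0.005 (full-scale multi-task ensembles of
  256-unit networks report values nearer 0.02), and because each of the
  ~75 delay units carries a large share of the output, the rate-behavior
  correlation is strong (grand mean ~0.2-0.4 rather than ~0.09).  In this
  regime trial-to-trial rate variance at the tuning-curve peak is dominated
  by rate-proportional noise rather than by drift of the activity bump, so
  the Fano-factor-by-location curve can peak at the preferred location
  instead of showing the M shape that drift-dominated variability produces
  (the correlation analysis, which isolates the drift mode directly, shows
  the M shape regardless).  The drifting-bump surrogate demonstrates that
  the analysis chain recovers the M-shaped curves, and their ablation,
  whenever drift does dominate.
- The logistic readout cannot attain the extreme target values exactly, so
  the loss has a nonzero floor; correctness is defined behaviorally, not by
  loss value.
- Fano factors are computed on rate variables, not spike counts; their
  absolute scale is far below that of spiking neurons and is interpreted
  only relatively, across conditions.
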