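# Methods

This note documents the models, estimators and numerical choices behind
`spikestab`, and what the synthetic-data experiments do and do not show.

## Irregularity measures

All four measures operate on consecutive interspike-interval (ISI) pairs
(I_i, I_{i+1}), which makes them insensitive to slow rate modulation: a
rate change that rescales neighbouring intervals together leaves the
pairwise contrast unchanged.

- **LvR** (default, R = 11 ms):
  `3/(n-1) * sum [1 - 4 I_i I_{i+1}/(I_i+I_{i+1})^2] * [1 + 4R/(I_i+I_{i+1})]`.
  The R-term compensates the *regularising* effect of refractoriness at
  high rates in biological trains.  On ideal (refractoriness-free) renewal
  ISIs this same term makes LvR *increase* with rate — the test suite pins
  this down rather than hiding it.  Rate-independence of LvR is a property
  of refractory spike trains, not of the formula in isolation.
- **Lv** = LvR with R = 0 (exact algebraic identity, tested).  Expected
  values: 0 for a clock train, 1 for Poisson, `3/(2k+1)` for a gamma
  renewal process of shape k.
- **IR** = mean |log ISI ratio|; **SI** = −(1/2) mean log of the
  geometric/arithmetic pair-mean ratio (≥ 0 by AM–GM).  Both are exactly
  invariant under time rescaling, as is Lv.

**Windowed estimation.**  At a few spikes/s a single trial contributes
almost no ISI pairs to a 100-ms window, so pairs are pooled across trials:
a pair contributes iff all three spikes defining it fall inside the
half-open window, and the estimate is the measure's scale factor times the
mean per-pair summand.  No partial-interval truncation is applied (it
would censor long intervals at window edges).  Windows with zero pairs
yield an explicitly undefined (NaN) value, never 0 — 0 means "perfectly
regular", which is a measurement, not a default.  Window-restricted pairs
are biased toward short ISIs, so windowed values sit above full-train
values for the same process; all contrasts in the package compare windowed
values against windowed baselines.

## Selectivity analysis

Spike counts in consecutive 100-ms bins are regressed on four ±1
categorical factors (final-goal horizontal/vertical, immediate-goal
horizontal/vertical) by OLS.  FGS(t) is the larger of the two final-goal
|t|-statistics divided by a critical value; IGS(t) likewise.  Because each
selectivity is a max over two regressors, the critical value is
Šidák-corrected (per-regressor level `1 − sqrt(1 − 0.05)`), so FGS ≥ 1
means "significant at P < 0.05 per bin" and the null exceedance rate is
calibrated at 5% (tested).

The F-I index `(IGS − FGS)/(IGS + FGS)` tracks the hand-off from
final-goal to immediate-goal coding.  Classification rules:

- **F-I neuron**: the index swings negative-to-positive; at the index
  maximum IGS is significant *and* backed by a significant neighbouring
  bin; FGS is significant somewhere before the transition.  The
  transition time is the last upward zero crossing of the index before
  its maximum, linearly interpolated between bin centres.
- **Final-goal neuron**: FGS significant in ≥ 3 consecutive bins, IGS in
  none (same run rule).
- Run-length 3 was chosen because over a ~34-bin trace, chance runs of
  two significant bins occur in 10–20% of unselective neurons; three-bin
  runs occur in <1%.  With these rules, default synthetic cohorts
  classify at ≥ 95% accuracy and transition times are recovered with
  median error below one bin (tested).

**Epoch contrasts.**  Windowed LvR is computed per neuron in 100-ms
epochs — start display [−800, −700), final-goal display [400, 500), delay
before transition [1100, 1200) relative to final-goal onset, and
[+200, +300) relative to each neuron's own transition — and population
contrasts are paired two-sided t-tests across neurons on
change-from-baseline.  All windows are half-open.

**Waveform typing.**  Two-class k-means on the Euclidean norm of the two
waveform durations; the smaller-norm cluster is putative inhibitory.  The
silhouette score is reported, with a low-separation warning below 0.75:
on 1-D data a two-means split of even a unimodal sample scores ~0.55–0.7
while genuinely bimodal duration norms score ~0.9, so 0.75 is the value
that discriminates the regimes.

## Population-rate network

Dynamics: `tau dx_i/dt = −x_i + sum_j w_ij S_ij(x_j) + b_i` with
tau = 20 ms, w_ij ∈ {+1, −1, 0}, and first-order Naka–Rushton gains
`S(x) = clip(B + c x/(theta + x), 0, 1)`.  Constant biases b_i keep
activities positive in inhibition-dominated topologies.  Negative
activities (transients) contribute zero drive.  Integration is classical
RK4 at dt = 0.05 ms; default runs are 60,000 steps (3 s).

**Noise.**  A Gaussian perturbation (sd sigma = 0.025, or 0.01 for the
three-node presets) is added to each gain output, redrawn once per
integration step and held through the four RK stages.  Holding the draw
through the stages keeps the effective noise dt-consistent and the run
bit-reproducible from a seed.  In the linear regime this is equivalent to
white noise of intensity sigma² dt/tau² per incoming edge, which is the
prediction the fluctuation tests check against a Lyapunov-equation
solution (within a factor of 2).

**Phase-model spiking.**  `tau' dphi/dt = 2*pi*max(x, 0)` with
tau' = 50 ms; a spike is emitted at each crossing of an integer multiple
of 2*pi, the crossing time interpolated linearly inside the step
(sub-dt precision matters: near-stable attractors produce LvR values of
order 1e-6 that step-quantised spike times would swamp).  Constant
activity x fires at x/tau': maximal activity ↔ 20 spikes/s, the
(0.5, 0.5, 0.5) attractor ↔ ~10 spikes/s.

## Stability indices

Fixed points are located by damped Newton iteration from a 21^n seed
lattice over (a slightly widened) [0, 1]^n, vectorised over seeds,
de-duplicated at 1e-6, residual tolerance 1e-8.  The Jacobian is analytic:
`J_ij = (−delta_ij + w_ij S'_ij(x*_j))/tau` with `S' = c*theta/(theta+x)²`
on the active branch and S' = 0 where the gain is clipped at the fixed
point (such edges are flagged).  Eigenvalues with |Re| < 1e-9/ms are
classified non-hyperbolic rather than stable.

- **MLE** = max real part of the Jacobian eigenvalues.  Two-node closed
  form: `(−1 + Re sqrt(eta12*eta21))/tau`; for excitation–inhibition
  pairings the root is imaginary and the MLE locks at −1/tau.
- **Stiffness** `s = prod(−lambda_i) = det(−J)` — the constant term of the
  characteristic polynomial, evaluated by LU determinant, *not* by
  eigen-decomposition (the eigensolver is the independent cross-check in
  the tests).  It is positive for every point attractor including
  complex-eigenvalue foci, equals `(1 − eta12*eta21)/tau²` for two nodes,
  and measures the depth of the local potential: at fixed noise,
  stationary variance shrinks as stiffness grows.  det(−J) is adopted for
  all n because it reproduces the two-node product definition and stays
  positive for attractors in any dimension.  A tau-normalised
  dimensionless form `s*tau^n` is reported alongside.
- On real-eigenvalue two-node sweeps the two indices are in one-to-one
  correspondence, `MLE = (−1 + sqrt(1 − s tau²))/tau`, verified to 1e-10
  on the s·tau² ∈ {1.0, 0.75, 0.5, 0.25, 0} grid (the boundary point is
  checked via det(−J) directly since it is no longer an attractor).

## Sweep presets

Text-book parameter values for the gain functions are not available, so
every preset is derived from printed constraints instead: attractor
locations (which fix firing rates through the phase model), effective
coupling slopes at the attractor (which fix MLE and stiffness), and the
declared bifurcation type, verified structurally by `classify_bifurcation`.
A gain with prescribed value v and slope eta at activity a is constructed
with theta = 0.5, `c = eta(theta+a)²/theta`, `B = v − c·a/(theta+a)`.

- *Mutual excitation / inhibition stability sweeps*: attractor pinned at
  (0.5, 0.5) (≈10 spikes/s); node-X2 slope swept so the coupling product
  runs 0.09 → 0.96, driving the normalised MLE −0.7 → −0.02 with the rate
  unchanged.
- *Excitation–inhibition sweep*: coupling product −1.0 → −0.05; MLE
  constant at −1/tau, normalised stiffness 2.0 → 1.05.
- *Three-node presets*: bidirectional pair couplings of equal slope
  (signs inhibition–excitation–excitation, or all-excitatory), attractor
  at (0.5, 0.5, 0.5), sigma = 0.01.  The symmetric coupling matrix has
  real eigenvalues {eta, eta, −2eta} (resp. {2eta, −eta, −eta}), so the
  normalised stiffness (1−eta)²(1+2eta) (resp. (1−2eta)(1+eta)²) falls to
  0 as the leading eigenvalue approaches the axis.  A directed ring with
  one inhibitory edge was rejected for this role: its stiffness 1+|P|
  *grows* toward the (Hopf-type) crossing.
- *Pitchfork scenario*: symmetric mutual inhibition, coupling product
  0.2 → 0.99 (critical) → 1.3 (past): the symmetric attractor
  destabilises and two winner-take-all attractors branch off.  The
  product is kept at 0.99 rather than 1.0 at the critical path point:
  with identical Möbius-form gains the two nullclines coincide entirely
  at product exactly 1, a degenerate line attractor.
- *Saddle-node scenario*: asymmetric mutual excitation (one biased node,
  one thresholded steep gain; fold at c ≈ 3.0528 located by bisection on
  the fixed-point count).  The tracked high-activity attractor collides
  with a saddle and vanishes; the state drops to the surviving low
  attractor.
- *Hopf scenario*: under these dynamics every two-node network has
  trace(J) = −2/tau < 0, so a two-node loop cannot undergo a Hopf
  bifurcation; the minimal loop that can is a three-node directed ring
  with one inhibitory edge (ring product P = −rho³), whose complex pair
  crosses the axis at rho = 2.  Past it a limit cycle (~15 Hz) appears.

`run_sweep` simulates each path point from its tracked attractor
(branch-matched within 0.25 in activity units — branch drift along the
fold path reaches 0.17 while post-critical basin hops exceed 0.32), with
per-repeat LvR (R = 11 ms) and rate over the full 3-s train, mean ± SEM
across seeded repeats.  Past the criticality the run starts at the
destination attractor when one exists — the post-transition epoch measures
the settled state, not the transit — or at the last tracked location when
none does (Hopf: the flow lands on the limit cycle).  Noise-free control
runs start at the same points; at subcritical points they produce exactly
regular trains (LvR = 0), which is the without-noise comparison.

Default experiment scale is 20 repeats × 60,000 steps per path point
(`--scale paper` selects 100 repeats).  Measured effects at sigma = 0.025
are small in absolute terms (ΔLvR of order 1e-6–1e-2) but many SEMs above
the seeded-repeat noise floor; all monotonicity claims are Spearman tests
at P < 0.01 over repeats × path points.

## Synthetic cohorts

Spike trains are time-rescaled gamma renewal processes: unit-rate gamma
intervals of shape kappa(t) in operational time, mapped through the
cumulative intensity of a piecewise-constant rate profile.  This
factorises rate (profile) and local irregularity (kappa, Lv ≈ 3/(2k+1))
exactly — the factorisation the rate-robust measures are designed to
exploit.  The shape in force at the previous spike governs the next
interval; kappa changes mid-interval take effect at the next draw.

Trial timeline (ms, relative to final-goal onset): start display −1000,
onset 0, delay 1000, go 2400.  Default profiles: baseline 5.7 spikes/s,
selectivity amplitude 10 spikes/s on the preferred goal quadrant,
kappa = 1 (Poisson-like) with a dip to 0.5 in the 400 ms before each F-I
neuron's transition (drawn uniformly from 1300–1500 ms so the dip always
covers the fixed pre-transition epoch).  Cohort sizes default to 148 F-I,
259 final-goal and 480 unselective neurons, 200 trials each.  Waveform
duration norms are a two-component Gaussian mixture (0.3 ± 0.03 vs
0.8 ± 0.05 ms, 25% narrow).

Generated spike times are quantised to 1 ms with ties merged, emulating
the resolution and absolute refractoriness of extracellular recordings.
This matters quantitatively: the continuous process at kappa = 0.5 emits
arbitrarily short intervals whose `4R/s` LvR term produces per-neuron
epoch values in the hundreds, making population contrasts unstable across
seeds; at recorded-data resolution the contrasts are stable and the LvR
magnitudes physiological.

**What passing tests show — and don't.**  The cohorts demonstrate that
the pipeline recovers programmed response classes, transition times and
epoch-wise irregularity schedules from data with realistic rates, trial
counts and measurement resolution.  They do not model bursting, serial
ISI correlations, non-stationary baselines, electrode drift or
cross-neuron correlations, so pipeline accuracy here is an upper bound on
real-data performance; the calibration tests (null exceedance, false-positive
classes) are the part most likely to transfer.

## Known limitations

- Stiffness compares networks of equal dimension; its units (1/ms^n)
  change with n, which is why the tau-normalised form is reported.
- The fold scenario's "critical" path point is near- rather than exactly
  at-criticality (the fold parameter is irrational); the declared
  bifurcation structure is verified by fixed-point counting, not by the
  path touching the singularity.
- `epoch_variability` pools ISI pairs within one 100-ms window per epoch;
  it does not correct for the short-ISI selection bias of windowing (all
  epochs share it, so contrasts are unaffected).
- The phase model has no spike-history dependence: identical activity
  traces yield identical trains up to phase origin.
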