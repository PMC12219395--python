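# Methods

## The system

A ring-shaped cargo is fixed to a rigid rod hinged at a pivot, so its
centre moves on a circle of radius `l_rod`; the angular position `theta`
is measured from the nest direction (`theta = 0`).  Up to `N_max` ants
occupy equally spaced sites on the ring.  Each attached ant is a *puller*
or a *lifter*; only pullers exert force, of fixed magnitude `f0` along
the ant's body axis.  The body axis of the ant at site `i` deviates by
`phi_i` from the outward site normal, clipped to `|phi| <= phi_max`
(52 degrees).  A newly attached ant is an *informed* puller that steers
toward the nest; it loses that information at rate `k_forget` and from
then on aligns with the force it feels.

Because the cargo never touches the floor, lifters exert no horizontal
force; their role is purely to be the reservoir from which pullers are
recruited.

## Stochastic dynamics

Event channels and rates (all per second):

| event       | rate                                  |
|-------------|---------------------------------------|
| attach      | `k_on * attach_boost` per empty site  |
| detach      | `k_off` per attached ant              |
| forget      | `k_forget` per informed ant           |
| reorient    | `k_ori` per attached ant              |
| role switch | `k_c * exp(-+ f_loc . p_hat / F_ind)` |

The role-switch exponent makes the two directions multiply to `k_c**2`
exactly: an Ising-like detailed structure in which `F_ind` (the
"individuality" force) is inversely related to the coupling between an
ant and the collective.  The simulation is a hybrid loop: a Gillespie
waiting time is drawn from the total rate, the overdamped motion is
advanced on a fixed `dt = 0.01 s` grid until that time elapses, the event
executes, and the rate table is rebuilt (also at pulse edges, where the
local force jumps).

Motion is overdamped and tangential: `gamma * v` equals the net
tangential force (ant pull plus the signed external force), and
`d(theta)/dt = v / l_rod`.  The damping `gamma` defaults to `3 * N_max`,
i.e. it grows linearly with the carrying group.

### The local force

The rates above depend on the *local force* `f_loc` an ant feels.  The
rod is rigid: radial force components are absorbed by the hinge, so the
force actually transmitted through the cargo is the net tangential force,
and the default (`local_force_model = "tangential"`) feeds exactly
`gamma * v` (as a vector along the path tangent) into the role-switch
exponents — the same quantity the mean-field rate equations use.  A
`"planar"` option couples the ants to the full planar force at the cargo
centre instead.  The tangential reading is the default because it is the
one that produces the observed order-disorder transition: under the
planar reading the informed ants' radial pull toward the nest dominates
`f_loc` whenever the cargo is near the nest line and tangential ordering
never develops (the N_max = 60 velocity distribution stays unimodal).

### Attachment saturation

Field recordings show the cargo essentially saturated with ants (a mean
of 54 ants on 60 sites for the largest cargo).  Bare per-empty-site
kinetics with `k_on = 0.021`, `k_off = 0.015` would give occupancy
`k_on/(k_on+k_off) = 0.58`.  The `attach_boost` multiplier (default 6.43)
raises the effective attachment rate so the stationary occupancy is 0.9,
reproducing the observed 54/60.  Tests of the bare two-state law set
`attach_boost = 1`.

### External pulses

A robot-like controller applies a rectangular tangential pulse when the
unwrapped cargo angle crosses the trigger angle (the nest line), directed
against the instantaneous motion.  Two termination rules are provided:

* `end_on_switch = True` (default): the pulse ends once the cargo has
  moved *with* the force for `switch_hold = 0.5 s` — modelling the
  cantilever clutch, which unloads as soon as the cargo aligns with the
  blade — or after `duration_max`, whichever comes first.
* `end_on_switch = False`: a fixed-duration rectangular pulse.

The termination rule matters for the susceptibility protocol: with
always-full-length pulses, a compliant small group is simply dragged
through an angle `F * dt / (gamma * l_rod)`, and since `gamma = 3 *
N_max` this rigid push grows as `1/N` and dominates the response curve,
which then decreases monotonically with group size.  With the clutch
rule, a group that yields immediately receives almost no net impulse —
as in the experiment — and the response measures what the *collective*
does with the injected information.

## Units

Forces are dimensionless "model units" internally; user-facing forces are
millinewtons with `force_unit_per_mN = f0 / 0.1 = 28`, anchoring one
ant-force `f0 = 2.8` to the ~0.1 mN pull of a single leader ant.  Under
this convention the ordered N_max = 60 state carries a net tangential
drive `gamma * v0 ~ 82` model units, i.e. about 29 ant-forces
(~2.9 mN-equivalent).  Leader-scale pulses (0.2-0.4 mN) therefore cannot
reverse the largest groups in this implementation; the measured 50%
switching force at N_max = 60 is ~1.5 mN-equivalent for 10 s pulses,
while at the critical size (N_max ~ 20) it is ~0.25 mN, squarely in the
leader-ant range.  `l_rod` is not constrained by the study and defaults
to 10 length units; angular observables are insensitive to it (speeds
and times are not, which is why trigger windows below are generous).

## Mean-field theory

With the cargo saturated, every ant feels the same force and the model
reduces to deterministic equations for `(theta, v)` with the sinh/cosh
structure given in `antcargo.meanfield`.  Linearising around rest gives
the control coefficient

    beta = f0 * N / (2 * F_ind) - 1,

a pitchfork bifurcation at the critical group size `N* = 2*F_ind/f0 =
20`: for `beta < 0` rest is stable (disordered), for `beta > 0` the
group moves at the spontaneous speed `v0` solving
`(f0*N/gamma) * tanh(gamma*v/F_ind) = 2*v` (bracketed root isolation on
`(0, f0*N/(2*gamma)]`).  The microscopic simulator reproduces `v0` at
N_max = 60 to within ~2%.

Rectangular pulses enter the velocity equation with Heaviside factors
plus delta terms at the edges; the integrator realises the deltas as
instantaneous velocity jumps of `-+ F_ext / gamma` (the formal integral
of `dv/dt` across the edge).

Integrating the linearised flow from `v0` to rest under a constant
opposing force yields the closed-form switching boundary

    F_ext(dt) = gamma * v0 * beta / (1 - exp(-2 * beta * k_c * dt)),

with the smooth `beta -> 0` limit `gamma*v0/(2*k_c*dt)` (evaluated via
`expm1`).  `fit_force_boundary` fits `(v0, beta)` to measured 50%-
switching points with `gamma, k_c` fixed; for fixed `beta` the model is
linear in `v0`, so a 1-D profile over `beta` seeds the joint least
squares.  The fit is well conditioned when the sampled `2*beta*k_c*dt`
range includes order-one values; for strongly ordered groups the curve
is nearly flat in `dt` and only the product `v0*beta` is identified.

## Susceptibility protocol

`chi = |<theta>_with - <theta>_without|` evaluated at `t' + dt + tau`,
with `tau = 5 s`.  Per group size, paired trials share a seed (common
random numbers): the control run is the identical realisation without
the pulse, so it crosses the nest line at the same instant and is read
at the same evaluation time; with `F_ext = 0` the pair is identical and
chi vanishes exactly.  Per-trial angles are mirrored so the applied
force always points in the negative-theta direction before averaging.
Pulse magnitudes are uniform in 0.25-0.35 mN; each pulse runs until the
group yields or a 10 s cap — the upper end of the experimental
force-application range — elapses, so the effective duration adapts to
the group's compliance through the clutch rule.
Trials are preceded by a 40 s relaxation (occupancy equilibrates with a
~7 s time constant) and the trigger is awaited for up to 250 s (an
ordered N_max = 60 cargo takes up to ~140 s to wind back to the nest
line).  The curve is normalised by its maximum; the default grid is
N = 2..70 in steps of 4 with 100+ repetitions per size.

Mechanism of the peak: small groups comply with the leader but carry no
order to retain the new direction (and, under the clutch rule, receive
almost no net impulse); large groups carry too much order for a
leader-scale force to flip; near `N*` the pulse can reverse the marginal
collective state and the order that remains sustains the new direction
through the delay `tau`.

## Track rendering and analysis

The synthetic-experiment stage renders trajectories the way the field
videos were measured: two angle tracks at 25 frames/s (cargo and robot
blade), where the blade angle adds the cantilever deflection
`F_ext / kappa` (default stiffness `kappa = 40 mN/rad`) and both tracks
carry independent Gaussian tracking noise (default sigma = 0.2 degrees).
The analysis stage then recovers, from tracks alone: the angular
velocity (central differences, one-sided at the ends), the force
timeline (`kappa * (theta_blade - theta_cargo)`), rectangular pulse
events (runs of `|F| > 0.05 mN`, merged across gaps < 0.5 s), switches
(omega sign reversals sustained >= 0.5 s, rejecting single-frame
flickers), the switching-probability-per-time-bin hazard, k-NN +
moving-window smoothed heatmaps over (F_ext, dt) (axes z-scored before
distances; default 20x20 grid, k = 15, 3x3 window), and the 50% boundary
by row-wise linear interpolation.  On noise-free tracks the pipeline
recovers pulse begin/end within one frame, magnitudes exactly, and all
switch/resist labels.

What the generator does not emulate: pixel-level tracking artefacts
(dropouts, identity swaps), the nonlinearity of the real cantilever
calibration, ant-to-ant behavioural heterogeneity, and group-size drift
within a trial.  Passing the analysis tests therefore demonstrates the
correctness of the measurement pipeline, not robustness to every failure
mode of real video tracking.

## Modality classification

The order parameter is the angular velocity: its distribution is
unimodal at zero in the disordered phase and bimodal at the two
spontaneous velocities in the ordered phase.  The classifier counts KDE
local maxima with prominence at least 10% of the global maximum, with
the KDE bandwidth set to 0.5 pooled standard deviations — coarse enough
to absorb the single-ant velocity quantisation of very small groups
(at N_max = 3 a single attached puller moves the cargo at a discrete
speed, producing spurious satellite peaks at finer bandwidths) while
keeping modes separated by about two standard deviations distinct.

## Numerical choices and degenerate inputs

* Gillespie channel selection is inverse-CDF over a flat rate table;
  float round-off at the top of the CDF falls back to the last positive
  channel.  Zero total rate returns an infinite waiting time.
* Attach on a full cargo and detach on an empty site are logic errors.
* The two engines (numba-compiled and interpreted) execute the same loop
  source on the same Mersenne-Twister stream and produce bit-identical
  trajectories; a test enforces this.
* Switch detection requires the reversed sign to persist 0.5 s
  (configurable) to reject jitter; trials whose trigger never fires are
  excluded from ensembles (and counted).
* The trigger is detected on the angle wrapped to (-pi, pi], so a cargo
  that has wound past a full turn still pulses at the nest passage; the
  crossing time is linearly interpolated within the step.
* `fit_force_boundary` rejects fewer than 3 distinct points or a
  degenerate duration axis.

## Problem sizes

Default analysis runs use 12-30 trials per condition, 300 s trajectories,
and 100-400 paired trials per group size for the susceptibility curve;
these sizes give standard errors a factor of several below the effect
sizes being tested while keeping every script in the minutes range on a
single core.

## Known limitations

* Under the f0 = 0.1 mN unit anchor, the simulated N_max = 60 group is
  more resilient (switching threshold ~1.5 mN) than the field
  observations it emulates (~0.4 mN); the discrepancy traces to the
  mean-field self-consistency of the saturated ordered state, which
  fixes `gamma * v0` at ~29 ant-forces, and cannot be removed by any
  single unit conversion without breaking the one-ant = 0.1 mN anchor.
  The switch/resist contrast and the response boundary are reproduced at
  forces scaled to the internal drive, and all critical-size phenomena
  (bifurcation at N = 20, susceptibility peak) are insensitive to the
  anchor.
* The k_ori reorientation event resets an uninformed ant's body axis
  toward the current local force; finer models (continuous alignment,
  partial turns) are not distinguished by any observable used here.
* The mean-field equations ignore number fluctuations; stochastic
  switching of large groups below the deterministic boundary is a
  finite-size effect present only in the microscopic simulator.
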