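# Methods

`tribochar` estimates the contact potential difference (CPD, `V_c`) of a
powder from a Faraday-cup charge-to-mass measurement taken after pneumatic
transport through a tube. The chain is: simulate how often and how hard
particles of a given size strike the tube wall, convert measured charge to
`V_c` through the condenser model of impact charging, and correlate `V_c`
with composition (here, protein content of sieved yellow-pea fractions).
This note records the models, the closures and numerical choices behind
them, and what the synthetic studies do and do not demonstrate.

## Condenser model of impact charging

Each particle-wall impact is treated as a transient parallel-plate
capacitor: charge flows across a critical gap `z0` driven by the contact
potential difference `V_c` between the two materials (difference of work
functions / elementary charge). After `n` impacts, far from saturation,

    dq/m = 6 eps0 V_c n k S / (pi D_p^3 rho_p z0)                     (linear law)

with charging efficiency `k`, maximum Hertzian contact area

    S = 1.36 k_e^(2/5) rho_p^(2/5) D_p^2 v_i^(4/5),
    k_e = (1 - nu_1^2)/E_1 + (1 - nu_2^2)/E_2,

and impact speed `v_i`. The saturating generalization (each fresh segment's
gain damped by charge already carried) is

    dq/m = (qm_inf - qm0) exp(-n_before/n0) (1 - exp(-n_segment/n0)),

which telescopes over consecutive segments and reduces to the linear law
for `n << n0`. The saturation parameters `qm_inf`, `n0` have no measured
values for this system, so that form is exercised only with synthetic
parameters.

**Scale caveat (important).** `k` and `z0` cannot be measured independently
here, so any absolute `V_c` this package reports is defined only up to the
factor `k/z0` (defaults `k = 1`, `z0 = 2.5e-7 m` fix a reporting scale).
Every correlation between `V_c` and composition is exactly invariant to
this scale — rescaling `k` or `z0` multiplies all `V_c` equally — and the
test suite asserts that invariance. Conclusions should therefore rest on
correlations and ratios, never on absolute `V_c`.

Elastic constants default to a dry plant-protein flour (`E1 = 2 GPa`,
`nu1 = 0.3`) against a PTFE wall (`E2 = 0.5 GPa`, `nu2 = 0.46`); they enter
`V_c` only through `S^(-1) ∝ k_e^(-2/5)`, a weak dependence.

## Gas phase

Fully developed pipe flow is described analytically instead of solving the
RANS equations: the trajectory model needs only the mean axial profile and
fluctuation statistics.

* Laminar (`Re < 2300` with auto-detection, overridable): the
  Hagen-Poiseuille parabola.
* Turbulent mean profile: Reichardt's composite law of the wall, rescaled
  so its area average equals the bulk velocity exactly. The friction
  velocity comes from the Blasius correlation `f = 0.316 Re^(-1/4)`,
  `u_tau = u_mean sqrt(f/8)`. The 1/7th-power-law profile is available as
  an option (`profile_model="power_law"`), but it has no viscous sublayer:
  it overestimates the axial gas speed at particle-radius distances from
  the wall by roughly a factor of seven at the rig condition, and
  near-wall residence time is precisely what controls repeated
  particle-wall collisions.
* Turbulence scalars from standard correlations: intensity
  `I = 0.16 Re^(-1/8)`, `kappa = 1.5 (u I)^2`,
  `eps = C_mu^(3/4) kappa^(3/2) / (0.07 D)` with `C_mu = 0.09`. The
  integral timescale used for Stokes-number classification is
  `tau_L = kappa/eps`; the eddy lifetime of the dispersion model is
  `tau_e = 0.30 kappa/eps` (classic discrete-random-walk value, exposed in
  `build_profile`).

At the rig condition (4.76 mm bore, 8.4 m/s) `Re ≈ 2650` and the friction
Reynolds number is only `R+ ≈ 99`: the flow is transitional (puff regime),
so all fully-turbulent correlations are stretched here. This is the single
largest source of quantitative uncertainty in the collision statistics.

## Particle transport

One-way-coupled Lagrangian tracking (dilute phase, volume fraction checked
against the 1e-6 one-way-coupling threshold): Schiller-Naumann drag

    Cd = 24/Re_p (1 + 0.15 Re_p^0.687)   (Re_p <= 1000),   0.44 above,

gravity `9.81 m/s^2` transverse to the axis (horizontal pipe), and
turbulent dispersion. Lift, Brownian motion and electrostatic migration are
omitted; drag and gravity dominate for 10-600 um grains. The integrator is
semi-implicit (drag implicit in the velocity update), stable when the step
approaches the particle response time `tau_p = rho_p d_p^2/(18 mu)`.

**Dispersion closure (default `wall_resolved`).** Axial and in-plane
tangential fluctuations follow the discrete-random-walk eddy model:
isotropic draws of rms `sqrt(2k/3)` held for
`min(tau_e, eddy transit time)`; the tangential component is additionally
damped linearly in `y+` near the wall (capped at the bulk value), because
persistent wall-parallel sliding on a curved wall otherwise registers
spurious curvature-induced contacts. The wall-normal component is a
normalized Ornstein-Uhlenbeck process with

* rms profile `sigma_r+(y+) = 0.005 y+^2 / (1 + 0.002923 y+^2.128)`
  (Kallio-Reeks DNS fit, capped at the bulk `sqrt(2k/3)`),
* timescale `T_L+ = 7.122 + 0.5731 y+ - 0.00129 y+^2`,
* the well-mixed drift `T_L dsigma_r^2/dy`, weighted by `1/(1 + tau_p/T_L)`
  for particle inertia. Without this drift an inhomogeneous random walk
  piles particles up against the wall — a documented pathology that we
  reproduced (thousands of spurious micro-bounces) before adding the term.

A homogeneous isotropic closure (`dispersion="homogeneous"`) is retained
for comparison; it overpredicts tracer-particle wall collisions by an
order of magnitude because real wall-normal fluctuations vanish at a wall.

**Wall interaction.** Contact at center distance `R - d_p/2`; specular
reflection with restitution 1.0 (configurable; the charging model assumes
elastic impacts). A contact is *counted* as a charging collision only when
the rebound can lift the particle one radius, `v_n >= sqrt(2 g d_p/2)`;
shallower contacts are rolling/sliding, not discrete impacts, and counting
them produces an inelastic-collapse-like artifact (unbounded micro-bounce
counts for settled grains). The logged impact speed is the pre-impact
outward normal speed, and the contact-area `v_i` is the mean over counted
impacts.

**Numerics.** The time step is the minimum of `tau_p/5`, `tau_e/3`, a
third of the near-wall OU timescale, a tenth of the wall-crossing time at
the reference transverse speed, and 1% of the axial transit; a
user-supplied step is shrunk with a warning if it fails `dt <= tau_p/5`.
Particles are released uniformly over the inlet disc with the local gas
velocity and an optional downward injection speed (0 by default; it is one
of the surrogate's inputs). A particle terminates on axial exit or after
`50 L/u_mean` (timed-out particles stay in the denominator of the mean).
The per-particle integration kernel is numba-compiled; each particle runs
an independent seeded stream derived from the run seed, so results are
bitwise reproducible for a fixed configuration.

## Surrogate

A database of mean collision numbers is built by running the tracker at
197 Latin-hypercube points over the six inputs (particle size 10-600 um,
density 1410-7850 kg/m^3, bore 2-6 mm, length 0.25-1.5 m, air velocity
6.5-36 m/s, injection vertical speed 0-1.2 m/s), 100 particles per point.
Features and target are min-max normalized on the training split
(70/15/15 = 137/30/30; train = floor(70%), validation = nearest-int(15%),
test = remainder). The surrogate is an ensemble of thirty 6-6-1 networks
(tanh hidden layer, linear output), each with its own seeded
initialization, trained by chunked L-BFGS with validation-based early
stopping (best-weights snapshot, patience 8 chunks of 150 iterations);
the prediction is the member mean. RMSE is always reported in
denormalized collision-number units. A 1-10 hidden-neuron sweep (5 seeded
repeats each) reproduces the expected underfitting shape: one neuron is
measurably worse than six.

Ensemble test RMSE on the default database is ~0.6-1.8 collisions
depending on the database seed — about 3% of the output range, dominated
by steep corners of the input space (small bore + high density + large
size), not by optimization quality (tripling the training budget moves it
little). The simulator's own Monte-Carlo noise per label (SEM with 100
particles) is ~0.3-0.4 collisions, so the surrogate sits above the label
noise floor; treat its point predictions accordingly.

## Characterization pipeline

Each sieved fraction is represented by its volume mean diameter D4,3 as a
monodisperse size (adequate for the narrow monomodal fractions; crude for
the wide, bimodal pan fraction). Rig velocity defaults to the 7 L/min
airflow converted through the bore area (≈ 6.56 m/s); an override supports
the 8.4 m/s condition the parameter studies use — the discrepancy between
the two is surfaced, not hidden. The transitional Reynolds number at rig
conditions is treated as turbulent by default (overridable). Per fraction:
collision number `n` and impact speed `v_i` from the tracker (or `n` from
the trained surrogate; `v_i` still comes from a tracker run, as the
surrogate predicts only collision numbers), `S` from the Hertz formula,
`V_c` by inverting the linear condenser law with the measured charge
converted as 1 nC/g = 1e-6 C/kg. Per-fraction tracker seeds derive from
the physical condition, not list position, so permuting input fractions
changes nothing. Fractions with zero predicted collisions are reported as
uncharacterizable rather than dividing by zero. Summary statistics:
Pearson and Spearman correlations plus an OLS line of `V_c` against
protein content, and of measured charge against predicted collision
number.

## What the synthetic studies show — and what they do not

The packaged measurement tables (seven sieved fractions; five material
densities) are real bench data; everything else the tests consume is
generated by the package itself. Synthetic size distributions are
log-normal mixtures (monomodal or bimodal with a sub-10-um fines peak) —
they emulate the qualitative shapes of laser-diffraction curves, not any
measured distribution. End-to-end tests inject known `V_c` values,
forward-model charges, and recover them to 1e-6 relative: that closed loop
validates the algebra and plumbing, not the physics. The collision
statistics themselves are closure-dependent: velocity and pipe-length
trends and the tracer limit are robust across closures; absolute collision
numbers for moderate-Stokes (40-100 um) grains, the short-pipe bound, and
the sign of the density trend at 100 um are not, because they hinge on the
balance between gravitational settling, near-wall resuspension and
transitional-flow intermittency that no fully-developed-flow closure pins
down. Humidity, particle shape and roughness, solids loading, charge
back-reaction on trajectories and wall fouling are outside the model.

## Problem sizes used in the shipped studies

Tracking runs use 100 released particles (collision-number statistics
stabilize near this count; the per-particle spread is reported as an SEM).
Reported collision numbers average 3-5 independent release seeds. The
surrogate database uses the full 197-point design; the neuron sweep uses
5 repeats per width. These sizes make the complete test suite and the
reproduction script each run in a few minutes on one CPU core.
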