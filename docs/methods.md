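# Methods

## Model

The package studies a network of N threshold-linear rate units with
synaptic currents h_i obeying

    tau dh_i/dt = -h_i + sum_j J_ij phi(h_j) + sqrt(N) I0 + dI_i(t),
    phi(x) = max(x, 0),

with i.i.d. Gaussian couplings J_ij ~ N(-J0/sqrt(N), g^2/N).  The
strongly negative mean coupling cancels the large static drive
dynamically (the balanced state): to leading order the population rate
obeys nu ~ I0/J0 with O(1/sqrt(N)) corrections.  The time-dependent drive
dI_i is sinusoidal, either *common* (identical across neurons) or
*independent* (i.i.d. uniform phase per neuron), or an Ornstein-Uhlenbeck
process (shared or per-neuron realisation).  The scientific question is
how large the drive amplitude I1 must be to suppress the intrinsic
chaotic fluctuations, quantified by the largest Lyapunov exponent
lambda_1, and why the answer differs so strongly between common and
independent input: common input enters the population-mean current, is
met by recurrent feedback -sqrt(N) J0 nu(t), and is therefore cancelled
up to a 1/sqrt(N) residue, whereas independent input drives the residual
fluctuations directly.

Two structural variants are included as controls: a sparsely connected
two-population excitatory-inhibitory network with fixed in-degree K per
presynaptic block (couplings ~ 1/sqrt(K), static drives ~ sqrt(K);
simulation and Lyapunov estimation only, no mean-field treatment), and
the classical non-balanced network with zero-mean couplings, zero static
input and tanh transfer, for which common and independent input behave
alike.

An optional 'tightness of balance' parameter K rescales J0 and I0 by
sqrt(K/N), which removes the explicit N-dependence of the mean-field
equations and mimics the number of synapses per neuron.

## Units and defaults

All times are in units of the membrane time constant tau (default 1);
frequencies and rates in 1/tau.  Defaults: J0 = I0 = 1, simulation step
dt = 0.01 tau (Heun; Euler selectable, and used in the learning
experiment), trajectory storage every 0.1 tau, Lyapunov renormalisation
interval 1 tau.  The divergence guard aborts integration when any
|h| > 1e6 sqrt(N).

## Gaussian moment kernels

All mean-field solvers reduce to bivariate-Gaussian expectations of phi
and of its derivative (a Heaviside step; phi'(0) = 0 by the subgradient
convention): E[phi], E[phi phi] and the orthant probability
P(X > 0, Y > 0).  One integral is always done analytically (conditional
closed forms), leaving a 1-D integral evaluated two ways: adaptive
quadrature (absolute tolerance 1e-10, relative 1e-8) for scalar calls,
and fixed-node Gauss-Legendre (80 nodes, 40-node preset for coarse runs)
vectorised over whole grid columns for the two-time solvers.  The two
agree to ~1e-14 over the parameter ranges the solvers visit; a
Monte-Carlo oracle provides an implementation-independent check.
Degenerate cases (zero variance, |correlation| = 1) reduce to 1-D
integrals rather than being rejected.

## Non-stationary mean-field solver

For common time-varying input the single-site statistics depend on
absolute time.  The closed system for the mean current m(t), the residual
autocorrelation c(t,s) and the auxiliary cross-correlation r(t,s) (with
source kernel q(t,s) = g^2 E[phi phi]) is integrated forward on a uniform
two-time grid:

* wavefront ordering with explicit Euler steps of size D = dt_grid/tau
  (default 0.02 tau; 0.05 tau presets for quick runs);
* at wavefront n the whole column r(., t_n) is rebuilt by an exact scan
  of the linear recurrence from its initial condition r(0, s) = 0 -- r
  (and l below) are *column* quantities whose evolution runs along the
  first time argument, which is why a row-wise update would be wrong;
* c is symmetric by construction (new column computed, row mirrored);
* initial conditions m = c = r = 0, a transient (default 20 tau) is
  discarded from all reported statistics.

The tangent kernel k(t,s), whose diagonal growth rate gives lambda_1,
obeys the same bidirectional structure with source kernel
q'(t,s) = g^2 P(both currents positive) and seed k(0,0) = 1.  lambda_1 is
extracted in three steps: (1) the diagonal log k(t,t) is smoothed by a
centred moving average over exactly one drive period, which removes the
cyclostationary modulation while leaving the linear trend intact; (2) a
regression with design (t, log t, 1) over the final half of the grid --
the log-time term absorbs the algebraic prefactor of the diagonal
(k(t,t) ~ t^alpha e^(2 lambda t), a boundary effect of forward
integration that otherwise biases the slope by O(1/t)); (3) the fitted
per-step growth rho is converted through the scheme's exact dispersion
relation rho = 1 - D + D sqrt(q), i.e. lambda_1 = (rho - 1)/(D tau),
rather than log(rho)/dt.  The inversion is what makes the silenced
network (-1/tau) and the constant-kernel closed form ((sqrt(q0)-1)/tau)
exact at any step size; for smooth kernels it agrees with the log form to
O(D).  A fit R^2 below 0.95 attaches a warning to the estimate.

Accuracy: halving the grid step changes lambda_1 by < 0.01/tau and nu(t)
by < 1%.  The only stiff regime is strong slow common drive
(I1 > sqrt(N) I0), where the un-silencing edge of nu(t) moves at a rate
~ sqrt(N) I1 f; resolving the edge to a few percent requires the 0.02 tau
grid (the 0.05 tau preset overshoots at the edge but barely moves
lambda_1).

A Monte-Carlo single-site oracle (sample paths of the Gaussian noise with
the current covariance, re-estimate the covariance, damped iteration)
provides an independent solution of the same self-consistency on coarse
grids and is used as the solver's acceptance oracle.

## Stationary mean-field theory

For constant input and for independent sinusoidal drive the statistics
are stationary and the two-time system collapses to
(1 - tau^2 d^2/dlag^2) c(lag) = q(lag), solved by damped fixed-point
iteration in Fourier space on a periodic lag grid (1024 points over
50 tau by default; the span is rounded up to whole drive periods so the
drive is commensurate with the circular domain; q and c are even in the
lag so only half the grid is evaluated).  The mean current solves the
balance condition 0 = -m + sqrt(N)(I0 - J0 nu(m)) by bracketed
root-finding each iteration.  Damping 0.7, residual tolerance 1e-8;
convergence slows near the autonomous transition (the relaxation mode
becomes marginal).  Warm-starting from a neighbouring solution, used
throughout the bisection searches, cuts the iteration count severalfold.

Independent sinusoidal drive adds, after low-pass filtering by the leak,
a deterministic per-neuron component of amplitude
A = I1/sqrt(1 + (2 pi f tau)^2) with uniform phase; phases are handled by
an explicit 32-point periodic quadrature rather than being folded into
the Gaussian (the drive is not Gaussian).  lambda_1 reuses the two-time
tangent machinery with the stationary kernel embedded on a grid
(step 0.05 tau, span >= 40 tau and >= 4 drive periods), so the stationary
and non-stationary paths share one exponent extractor.  When the
embedding grid extends past the lag grid's half-span, the kernel is
continued with its asymptotic form: the last whole drive period repeated
periodically (a constant clamp would freeze the persistent entrainment
oscillation at an arbitrary phase and badly bias lambda_1 at high drive
frequency).

In the fixed-point regime (g < sqrt(2)) the iteration converges to a flat
c profile (frozen heterogeneous currents) and the embedded exponent
reproduces the closed form g sqrt(Phi(m/sqrt(c0))) - 1; the computed
transition of the autonomous network sits at g = sqrt(2) to within 5e-3.
By positive homogeneity of the threshold-linear transfer, the autonomous
exponent is independent of the (positive) input scale; `lambda1_const(g)`
caches it per gain.

## Time-averaged autocorrelations

The time-averaged rate autocorrelation Cbar(lag) — computed from sampled
trajectories and, on the theory side, from the two-time grid via the
bivariate kernel — averages the product of rates at fixed lag over a t'
window that is (a) the same for every lag and (b) a whole number of drive
periods under periodic input.  Both conditions matter: a lag-dependent or
partial-period window weights the cyclostationary modulation unevenly and
biases the estimate by up to ~10% of Cbar(0) in the driven regimes, which
would swamp the theory-simulation comparison.

## Quasi-static theory

For slow common drive (tau f << 1) the exponent is the duration-weighted
average of silent episodes (total input negative, lambda_local = -1/tau)
and chaotic episodes (lambda_local = lambda1_const(g)):

    lambda_1 = -(1/tau) P_silent + lambda1_const(g) (1 - P_silent),

with P_silent = arccos(sqrt(N) I0/I1)/pi for sinusoidal drive (zero below
the threshold amplitude sqrt(N) I0) and
P_silent = erfc(sqrt(N) I0/sqrt(2 tau_s D))/2 for OU drive of intensity D
and correlation time tau_s (stationary variance D tau_s).  Setting
lambda_1 = 0 gives

    I1crit = sqrt(N) I0 sec(pi lambda_c/(1/tau + lambda_c)),
    Dcrit  = N I0^2/(2 tau_s) [erfcinv(2 lambda_c/(1/tau + lambda_c))]^(-2),

both diverging as lambda_c -> 1/tau (slow input of any strength can no
longer suppress chaos).  The 1/pi normalisation of P_silent and the
placement of the inverse square on erfcinv are fixed by the requirement
that the amplitude formulas be exact roots of the episode-averaged
exponent; both identities are enforced by tests to 1e-10 / 1e-8 rather
than assumed.  The high-frequency attenuation factor
1/sqrt(1 + (2 pi f tau)^2) gives the complementary linear growth of
I1crit at large f.

## Lyapunov estimators

Tangent method: u evolves under the linearised flow alongside the
trajectory; the leak is integrated with an integrating-factor Heun scheme
(exact factor e^(-dt/tau)), so a silenced network yields -1/tau to
machine precision; renormalisation every tau; error bars are batch-mean
standard errors over 10 segments; the first 50 tau of tangent dynamics
are discarded on top of the state transient.  Replica method: two
trajectories with identical couplings and identical input realisation,
separation rescaled to epsilon = 1e-8 sqrt(N) every tau.  The two methods
agree within their combined errors; the replica estimate is insensitive
to epsilon over 1e-6..1e-9.  A linear-transfer surrogate ties the tangent
estimator to the exact spectral abscissa of (-I + J)/tau.  The sliding-
window local exponent exposes the silent/chaotic episode structure under
slow strong drive.

## Critical amplitude search

Bisection on the zero of lambda_1(I1) to 1% relative precision, with
geometric bracket expansion when the initial bracket does not straddle
the root.  For noisy simulation-based exponents, sign decisions use a
two-standard-error guard; on ambiguity the estimate is recomputed with a
doubled measurement window (up to twice).  Sweeps redraw couplings per
realisation and aggregate per-point.

## Learning experiment

full-FORCE with per-neuron recursive least squares: the driven teacher's
total incoming currents are recorded over a phase-locked window of 10
drive periods (Euler, dt = 0.01, transient >= 50 tau rounded to whole
periods); the student (same architecture, static input only) cycles over
that window, with one shared inverse-correlation matrix P = I/beta
(beta = 1) updated every step driving rank-one updates of all coupling
rows and of the readout.  Testing is interleaved: after each pass the
student runs autonomously for 5 whole periods (state carried through, so
it stays near the target trajectory and the drive phase stays aligned);
training stops when the normalised running training error falls below
1e-2 or after the pass limit.  The reported test error is the normalised
squared readout error over 50 output periods.  Cycling a 10-period window
is exact for an entrained (periodic) teacher and an approximation for a
chaotic one; since chaotic teachers are precisely the ones that fail to
be learned, the approximation does not affect the conclusions.

Total training duration is governed by the stopping criterion; in
practice a suppressed teacher converges in one or two passes.  Continuing
to train well past the criterion can slightly degrade the 50-period test
error (slow drift of the learned limit cycle), which is why the early
stop is part of the protocol.

## Synthetic problem sizes

The package generates all of its own data; there is no external input.
The test-suite runs the study conditions at reduced network sizes and
durations chosen so that mean-field and simulation error bars still
separate the effects of interest: N = 2000 for theory-vs-simulation
comparisons (5 coupling realisations, medians), N = 500..4000 for the
size-scaling of the critical amplitude, N = 500 for the learning
experiment, N = 1000 for the tanh control, measurement windows of
100-250 tau for simulated exponents.  What passing these tests shows is
agreement between independent computational routes (simulation vs two
mean-field solvers vs closed forms) under the model's own assumptions;
they do not probe robustness to features real data would add (finite
observation noise, heterogeneous time constants, structured rather than
random connectivity).

## Known limitations

* The mean-field solvers are specific to the threshold-linear transfer;
  the tanh control is handled by simulation only, as is the sparse E-I
  variant (no analytical treatment of the two-population network).
* The two-time solver's memory grows as the grid squared (~160 MB at
  4400 points); slow-drive studies at f << 0.01/tau need either coarse
  steps or a windowed reformulation that is not implemented.
* The non-stationary solver assumes a single common drive realisation
  per solve for OU input (quenched drive); averaging over realisations
  is left to the caller.
* Matrix-level identification of teacher couplings by RLS is limited to
  the regressor subspace the student trajectory excites; functional
  recovery on the attractor is complete, but weights in never-excited
  directions retain their initialisation.
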