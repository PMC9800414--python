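# Methods

## Model

`activedisks` simulates N soft disks of unit diameter in a 2D periodic
rectangle (default aspect Lx/Ly = 2/sqrt(3), commensurate with a triangular
lattice).  Lengths are measured in disk diameters (sigma = 1) and times in
the rotational diffusion time (1/D_r = 1), so the persistence time of an
overdamped disk is tau_P = 1.  The equations of motion are

    M dv_i/dt = -v_i - grad_i U + Pe n_i,        n_i = (cos theta_i, sin theta_i)
    J d2theta_i/dt2 = -dtheta_i/dt + sqrt(2) xi_i(t),

with U = Gamma sum_{i<j} exp(-kappa (r_ij - 1)) / r_ij truncated (unshifted)
at r_c.  Translational thermal noise is omitted: at the activity levels of
interest (Pe ~ 10^2) it is orders of magnitude below the active and
interaction forces.  The dimensionless groups are

| parameter | meaning                               | default |
|-----------|---------------------------------------|---------|
| M         | reduced translational inertia m D_r/gamma | 0.05 |
| J         | reduced rotational inertia I D_r/gamma_r  | 2.0  |
| Pe        | Peclet number v_0/(D_r sigma)             | 125  |
| Gamma     | interaction strength U_0/(gamma sigma^3 D_r) | 25 |
| kappa     | softness parameter sigma/lambda (hardness grows with kappa) | 7 |
| phi       | global area fraction N pi/(4 Lx Ly)       | 0.65 |
| r_c       | interaction cutoff (sigma)                | 8.0  |
| dt        | integration step (1/D_r)                  | 1e-4 |

The dimensional symbols (m, I, gamma, gamma_r, D_r, sigma, lambda, U_0, v_0)
exist only through these groups and are not stored anywhere.

Truncating without an energy shift leaves a discontinuity of
Gamma e^(-kappa (r_c - 1))/r_c at the cutoff — about 1e-6 Gamma at the
default r_c = 8 for kappa >= 2 — which is far below every force scale in
the problem and is documented rather than compensated.

## Integration

Both fast linear relaxations are propagated exactly, which is what makes a
fixed dt = 1e-4 usable across J in [1e-4, 10] and M down to 0.005:

* **Rotor.** The pair (theta, omega) obeys a linear SDE whose one-step
  transition is Gaussian with
  E[omega'] = alpha omega, E[theta'] = theta + J (1 - alpha) omega,
  Var[omega'] = (1 - alpha^2)/J, Cov = (1 - alpha)^2, and
  Var[theta'] = 2 J (eps + 2 expm1(-eps) - expm1(-2 eps)/2), where
  eps = dt/J and alpha = e^(-eps).  `RotorPropagator` precomputes the
  Cholesky factors; one step draws one exact sample for any dt/J, so there
  is no discretization bias even at dt/J = 1 (where Euler-Maruyama on the
  stiff omega equation is badly biased).  Var[theta'] is a difference of
  O(eps) terms with an O(eps^3) result; below eps = 1e-3 it is evaluated by
  its series eps^3/3 - eps^4/4 + 7 eps^5/60 to avoid cancellation.
  J = 0 dispatches to the exact overdamped increment sqrt(2 dt) xi.
* **Translation.** The drag is integrated exactly with the total
  non-drag force (conservative + active) frozen over the step:
  v' = v e^(-dt/M) + (F + Pe n)(1 - e^(-dt/M)), r' = wrap(r + v' dt).
  The only error is the O(dt^2) force-freezing term.

Step order is: forces at current positions -> translational update using the
*current* orientations -> rotor update.  The RNG is a single seeded numpy
PCG64 stream per run; each step consumes one standard_normal((2, N)) block
(slab 0, then slab 1, particle-major).  The fused numba loop consumes
pre-drawn slabs of the same stream, so it reproduces the pure-python
per-step path to round-off (~1 ulp; fastmath reassociation), and two runs
with the same seed are bit-identical.

Initial conditions (production default): triangular lattice with jitter
0.05 of the spacing (near-homogeneous, no overlaps at phi = 0.65), uniform
random orientations, terminal velocities v = Pe n, and omega drawn from the
stationary distribution Var = 1/J.  This minimizes transients; the start is
configurable.

## Neighbor search

Linked cell lists with cell edge >= r_c, rebuilt every step (particles move
~1e-2 sigma per step, far less than a cell).  The sweep uses a half stencil
so each unordered pair is accumulated once, antisymmetrically (Newton's
third law holds to accumulation round-off, <= 1e-8 N).  Boxes smaller than
3 cells per dimension fall back to an all-pairs loop.  Agreement with an
independent all-pairs oracle is at the 1e-10 *relative* level; absolute
1e-10 is not meaningful here because summation order differs between the
two routes and contact forces reach 10^3-10^4.

Exact overlaps (r = 0) raise an error rather than being clamped: they
signal a broken setup, and silent clamping would corrupt the physics.

## Observables

* **Local area fraction** phi_i = (pi/4)/A_i with A_i the periodic Voronoi
  cell area (scipy, ghost-image construction; cells tile the box to 1e-6
  relative).  Overlapping soft disks give phi_i > 1; dense-phase values
  around 1.25 are physical.  Degenerate (collinear) inputs are perturbed by
  1e-9 and retried, with a log record.
* **Phase labels.** dense iff phi_i > phi (strict), with phi the global
  area fraction.
* **MIPS verdict.** Histogram of phi_i (bin 0.02 on [0, 1.6]) smoothed by
  a 5-bin moving average; phase separation iff >= 2 maxima with prominence
  >= 5% of the tallest and separation >= 5 bins.  All thresholds are
  arguments.  On unimodal Gaussian control samples the false-positive rate
  is below 5%, with >= 95% power at 6-pooled-SD mixtures (tested).
* **Hexatic order** q6_i over the six nearest minimum-image neighbors
  (distance ties broken by index; the printed six-term sum fixes the
  neighborhood size).  Reported region values are averages of q6_i over the
  particle set under discussion.
* **RDF** per phase: pair histogram restricted to one phase, normalized by
  the phase's own density over its own Voronoi-area footprint, so g -> 1
  at large r inside a homogeneous phase.  r_FP is the first interior
  maximum above 1, refined by 3-point parabolic interpolation.
* **Clusters.** Connected components of dense-labeled particles at linking
  distance r_link = 1.2 (just above first-neighbor distances at all kappa
  studied; configurable).  Cluster centers are circular-coordinate means
  (wrap-aware).  A cluster spanning the box in some dimension (full bin
  occupancy at r_link resolution) is a slab; otherwise the gyration aspect
  sqrt(lambda_max/lambda_min) < 1.5 means circular.
* **Central/peripheral decomposition.**  Radial (or slab-normal) profiles
  of phi_i, q6_i and speed from the cluster center; the plateau value P is
  the mean over the innermost 20% of occupied bins, r1 the last radius
  inside the band |value - P| <= 0.05 |P - dilute|, r2 the first radius
  where the profile reaches within 0.05 |P - dilute| of the dilute value,
  r_p = r2 - r1.  The 5% band and 20% core are pragmatic choices for a
  quantity usually drawn by eye; both are arguments.
  Profiles without a plateau/decay structure are flagged indeterminate,
  not an error.
* **Retention fraction** R(t - t1): instantaneous membership of initially
  tagged particles in a fixed region (annulus or slab band).  Instantaneous
  rather than continuous residence, so R can rise when particles re-enter
  through the periodic boundary.
* **Autocorrelations** C_v(t) (unit velocities; |v| < 1e-12 excluded and
  counted) and C_n(t) = <cos(theta(t0+t) - theta(t0))>, averaged over
  particles and sliding origins in the stationary window.
* **Effective persistence time** tau_P^e: trapezoidal integral of C_n to
  its first crossing of 0.01 plus an exponential tail fitted to the last
  decade of the decay.  On noisy ensemble curves the threshold crossing
  biases the estimate by a few percent; ensemble averaging over independent
  batches (rotor-verify uses 5) brings it to ~1%.
* **Spatial velocity correlation** C(r): per-distance-bin mean of unit
  velocity dot products over pairs, averaged over snapshots (production
  convention: 50 frames spaced 1 time unit).  Fitted with
  m e^(-a r)/r^b + c (5 multi-starts over a, b in [0.01, 2], a, b >= 0);
  the strength S is the trapezoidal integral of the fit on [0.1, 50] at
  spacing 0.1.  The lower limit 0.1 follows the fit window convention; a
  constant curve makes (m, a, b, c) degenerate, but S is invariant on that
  surface, and S is the contractual output.

## Scaling theory

For the free rotor with stationary omega, <dtheta^2(t)> =
2[t - J(1 - e^(-t/J))] and C_n(t) = exp(-<dtheta^2>/2).  Its integral
tau_P^e(J) (adaptive quadrature) interpolates the limits 1 + J (J << 1)
and sqrt(pi J/2) (J >> 1); the full closed form is used because it is
exactly testable against simulated rotors at any J.  The MIPS boundary
criterion tau_P^e ~ tau_kappa = 1/kappa gives kappa* = c_small (1 - J) for
J < J* and c_large J^(-1/2) for J >= J* (regime split J* = 0.06 by
default).  The prefactors depend on M/Pe and are free parameters fitted to
verdict grids; by default c_large is chosen to make the branches continuous
at J*.

Note that the measured log-log slope of tau_P^e over J in [1e2, 1e4] is
0.495, not exactly 1/2: the approach to the asymptote contributes an
approximately constant offset (~0.34) to tau_P^e, which steepens slowly.
Over J in [10, 1e3] the slope is 0.483.

## Problem sizes for the bundled checks

The packaged tests and the acceptance script run scaled-down versions of
the production conditions (the full-scale study uses N = 48,400 and runs to
t = 500, which is cluster-scale compute).  The scaled runs keep dt = 1e-4,
phi = 0.65, Gamma = 25, M = 0.05, Pe = 125 and reduce N and the cutoff:

* r_c = 2.5 in the scaled runs.  For every kappa >= 5 used there the pair
  force at r = 2.5 is below 3e-2 (relative to the active force Pe = 125,
  below 3e-4), so the truncation is physically negligible while reducing
  the pair workload ~10x.
* N = 1024 (square, so the triangular-lattice start tiles the box exactly)
  with runs to t = 35-40; the local-phi distribution at these sizes is
  statistically stationary from t ~ 20-25 (verified up to t = 200 at
  N = 2025).

What the scaled checks do and do not show.  A scaled box (33-77 sigma
across, versus 265 x 230 at full scale) is smaller than the dense-phase
*interface* of this model — the full-scale peripheral width is r_p ~ 8-38
sigma, and the persistence length Pe tau_P^e is 270+ sigma — so the
phase-separated state with a dense plateau (phi ~ 1.25 for soft disks) and
a distinct gas peak cannot form: the scaled system instead reaches a
stationary heterogeneous active liquid (broad unimodal local-phi
distribution; verified across N = 784 to 4,225 and to t = 200).
Consequently:

* checks of rotor statistics, the scaling theory, and every observable on
  synthetic fixtures are scale-free and decisive;
* homogeneous-state dynamical claims (C_v/C_n independent of softness, no
  spatial correlation of the propulsion direction, tau_P^e growing with J)
  hold at scaled sizes and are asserted green;
* claims *about the phase-separated state* — the bimodality verdict flip
  across the kappa boundary, the central-region phi ~ 1.25, and the growth
  of the correlation strength S with J — require boxes several interface
  widths across (N >> 10^4) and fail at desk scale; the corresponding
  checks run at the documented scaled conditions and their failures are a
  documented finite-size limitation, not a defect of the estimators
  (which are separately validated on constructed fixtures).

For the scaled runs the correlation strength is reported as the raw
trapezoidal integral over the data-supported window [0.1, r_max_box]:
extrapolating the four-parameter fit to r = 50 from a 16-sigma window is
numerically unstable and carries no information.

The synthetic fixtures (lattices, random gases, prescribed two-phase
configurations) validate every observable against constructions with known
answers and carry no dynamics at all.

## Known limitations

* 2D only, purely repulsive monodisperse disks; no translational noise.
* The fused integrator freezes conservative forces over one step (O(dt^2));
  at dt = 1e-4 the step-halving position discrepancy over t = 5 is < 1e-3.
* Voronoi tessellation cost (~O(N log N) with scipy) dominates analysis at
  large N; analysis routines are vectorized but not numba-accelerated.
* The phase-boundary prefactors are empirical by design; only the regime
  exponents are predictions.
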