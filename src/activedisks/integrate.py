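"""Time integration of the coupled translational / rotational Langevin system.

Two stiffness sources make naive Euler-Maruyama unusable at the default
dt = 1e-4: the rotor relaxes on the scale J (studied down to J = 1e-4, i.e.
dt/J = 1) and the velocity on the scale M (down to 0.005).  Both linear parts
are therefore propagated *exactly*:

* the inertial rotor  J d(omega)/dt = -omega + sqrt(2) xi(t),  d(theta)/dt =
  omega  is a linear SDE whose one-step transition is a 2D Gaussian with known
  mean and covariance; :class:`RotorPropagator` precomputes its Cholesky
  factors so one step draws one exact sample for any dt/J ratio;
* the translational drag is integrated exactly with the conservative force and
  the active force held constant over the step (exponential / exact-drag
  update), leaving an O(dt^2) force-freezing error only.

RNG contract: a single seeded numpy ``Generator`` per run; each step consumes
one ``standard_normal((2, N))`` block (slab 0 then slab 1, particle-major).
The fused numba fast path consumes identical pre-drawn slabs, so it is
stream-identical with the pure-python :func:`step` reference path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import Box, ParticleState, SimParams, total_forces, wrap_positions

__all__ = [
    "RotorPropagator",
    "rotor_step",
    "translational_step",
    "step",
    "run",
    "Trajectory",
]


def _bracket(eps: float) -> float:
    """Stable evaluation of eps - 2(1 - e^-eps) + (1 - e^-2eps)/2 = eps^3/3 - ...

    Direct subtraction loses all digits for eps << 1 (the result is O(eps^3));
    below 1e-3 the series is exact to double precision.
    """
    if eps < 1e-3:
        return eps**3 / 3.0 - eps**4 / 4.0 + 7.0 * eps**5 / 60.0
    return eps + 2.0 * math.expm1(-eps) - 0.5 * math.expm1(-2.0 * eps)


@dataclass(frozen=True)
class RotorPropagator:
    """Exact one-step Gaussian transition of (theta, omega) for the free rotor.

    For J > 0, with alpha = exp(-dt/J):

        E[theta'] = theta + J (1 - alpha) omega
        E[omega'] = alpha omega
        Var[theta'] = 2 J (eps + 2 expm1(-eps) - expm1(-2 eps)/2),  eps = dt/J
        Var[omega'] = (1 - alpha^2) / J
        Cov[theta', omega'] = (1 - alpha)^2

    The stationary variance of omega is 1/J; as J -> 0 the theta increment
    tends to sqrt(2 dt) * xi (overdamped rotor), which is dispatched exactly.
    """

    J: float
    dt: float
    alpha: float = field(init=False)
    theta_drift: float = field(init=False)
    var_theta: float = field(init=False)
    var_omega: float = field(init=False)
    cov: float = field(init=False)
    l11: float = field(init=False)
    l21: float = field(init=False)
    l22: float = field(init=False)

    def __post_init__(self) -> None:
        if self.J < 0:
            raise ValueError("J must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.J == 0.0:
            # Overdamped: theta' = theta + sqrt(2 dt) xi; omega unused.
            object.__setattr__(self, "alpha", 0.0)
            object.__setattr__(self, "theta_drift", 0.0)
            object.__setattr__(self, "var_theta", 2.0 * self.dt)
            object.__setattr__(self, "var_omega", 0.0)
            object.__setattr__(self, "cov", 0.0)
            object.__setattr__(self, "l11", math.sqrt(2.0 * self.dt))
            object.__setattr__(self, "l21", 0.0)
            object.__setattr__(self, "l22", 0.0)
            return
        eps = self.dt / self.J
        alpha = math.exp(-eps)
        one_m_a = -math.expm1(-eps)
        var_theta = 2.0 * self.J * _bracket(eps)
        var_omega = -math.expm1(-2.0 * eps) / self.J
        cov = one_m_a * one_m_a
        l11 = math.sqrt(var_theta)
        l21 = cov / l11
        arg = var_omega - cov * cov / var_theta
        l22 = math.sqrt(max(arg, 0.0))
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "theta_drift", self.J * one_m_a)
        object.__setattr__(self, "var_theta", var_theta)
        object.__setattr__(self, "var_omega", var_omega)
        object.__setattr__(self, "cov", cov)
        object.__setattr__(self, "l11", l11)
        object.__setattr__(self, "l21", l21)
        object.__setattr__(self, "l22", l22)

    @property
    def stationary_omega_std(self) -> float:
        return math.sqrt(1.0 / self.J) if self.J > 0 else 0.0


def rotor_step(
    theta: np.ndarray,
    omega: np.ndarray,
    propagator: RotorPropagator,
    rng: np.random.Generator,
    noise: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One exact sample of the rotor transition for every particle.

    `noise`, if given, must be a (2, N) standard-normal block (used by the
    determinism tests to replay a stream); otherwise it is drawn from `rng`.
    """
    p = propagator
    if noise is None:
        noise = rng.standard_normal((2, theta.shape[0]))
    g1, g2 = noise[0], noise[1]
    if p.J == 0.0:
        return theta + p.l11 * g1, np.zeros_like(omega)
    theta_new = theta + p.theta_drift * omega + p.l11 * g1
    omega_new = p.alpha * omega + p.l21 * g1 + p.l22 * g2
    return theta_new, omega_new


def translational_step(
    state: ParticleState,
    forces: np.ndarray,
    M: float,
    Pe: float,
    dt: float,
    box: Box,
) -> None:
    """Exact-drag velocity/position update, in place; deterministic given theta.

    v' = v e^(-dt/M) + (F + Pe n) (1 - e^(-dt/M));  r' = wrap(r + v' dt).
    """
    total = forces + Pe * state.n_hat
    if not np.all(np.isfinite(total)):
        bad = int(np.argwhere(~np.isfinite(total))[0][0])
        raise FloatingPointError(
            f"non-finite force on particle {bad} at t={state.t}"
        )
    em = math.exp(-dt / M)
    state.vel = state.vel * em + total * (1.0 - em)
    state.pos = wrap_positions(state.pos + state.vel * dt, box)


def step(
    state: ParticleState,
    params: SimParams,
    box: Box,
    rng: np.random.Generator,
) -> ParticleState:
    """Advance one step: forces -> translational update -> rotor update.

    Reference path; bit-identical to the fused numba loop given the same
    noise stream.
    """
    new = state.copy()
    forces = total_forces(new.pos, box, params.Gamma, params.kappa, params.r_c)
    translational_step(new, forces, params.M, params.Pe, params.dt, box)
    prop = RotorPropagator(params.J, params.dt)
    noise = rng.standard_normal((2, new.n))
    new.theta, new.omega = rotor_step(new.theta, new.omega, prop, rng, noise)
    new.t = state.t + params.dt
    return new


@dataclass
class Trajectory:
    """Uniformly sampled sequence of snapshots from one run."""

    times: np.ndarray      # (T,)
    pos: np.ndarray        # (T, N, 2)
    vel: np.ndarray        # (T, N, 2)
    theta: np.ndarray      # (T, N)
    omega: np.ndarray      # (T, N)
    box: Box
    params: SimParams

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n(self) -> int:
        return self.pos.shape[1]

    def frame(self, i: int) -> ParticleState:
        return ParticleState(
            t=float(self.times[i]),
            pos=self.pos[i].copy(),
            vel=self.vel[i].copy(),
            theta=self.theta[i].copy(),
            omega=self.omega[i].copy(),
        )

    @property
    def sample_interval(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


# Noise slabs are generated in sub-chunks of at most this many steps to bound
# memory (2 * N * chunk doubles).
_MAX_NOISE_DOUBLES = 4_000_000


def run(
    state: ParticleState,
    params: SimParams,
    box: Box,
    rng: np.random.Generator,
    callback=None,
) -> Trajectory:
    """Integrate to t_end, recording snapshots every snapshot_every time units.

    The initial state is snapshot 0.  The final recorded time is within dt/2
    of t_end.  `callback(frame_index, state)` is invoked at every snapshot
    (used for streaming snapshots to disk).
    """
    dt = params.dt
    n_steps_total = int(round(params.t_end / dt))
    steps_per_snap = max(1, int(round(params.snapshot_every / dt)))
    n_snaps = n_steps_total // steps_per_snap + 1

    n = state.n
    times = np.empty(n_snaps)
    pos = np.empty((n_snaps, n, 2))
    vel = np.empty((n_snaps, n, 2))
    theta = np.empty((n_snaps, n))
    omega = np.empty((n_snaps, n))

    cur = state.copy()
    prop = RotorPropagator(params.J, dt)
    em_t = math.exp(-dt / params.M)
    sqrt2dt = math.sqrt(2.0 * dt)

    def record(i: int) -> None:
        times[i] = cur.t
        pos[i] = cur.pos
        vel[i] = cur.vel
        theta[i] = cur.theta
        omega[i] = cur.omega
        if callback is not None:
            callback(i, cur)

    record(0)
    max_chunk = max(1, _MAX_NOISE_DOUBLES // (2 * n))
    steps_done = 0
    frame = 1
    while steps_done < n_steps_total:
        # integrate up to the next snapshot boundary
        until = min(steps_done + steps_per_snap, n_steps_total)
        while steps_done < until:
            k = min(max_chunk, until - steps_done)
            noise = rng.standard_normal((k, 2, n))
            status, idx, at = _kernels.run_chunk(
                cur.pos, cur.vel, cur.theta, cur.omega, noise,
                box.Lx, box.Ly, params.Gamma, params.kappa, params.r_c,
                params.Pe, em_t, dt,
                params.J == 0.0, prop.alpha, prop.theta_drift,
                prop.l11, prop.l21, prop.l22, sqrt2dt,
            )
            if status == _kernels.OVERLAP:
                raise FloatingPointError(
                    f"exact particle overlap involving particle {idx} "
                    f"at step {steps_done + at}"
                )
            if status == _kernels.NONFINITE:
                raise FloatingPointError(
                    f"non-finite force on particle {idx} "
                    f"at step {steps_done + at}"
                )
            steps_done += k
        cur.t = state.t + steps_done * dt
        if steps_done % steps_per_snap == 0 and frame < n_snaps:
            record(frame)
            frame += 1

    return Trajectory(
        times=times[:frame], pos=pos[:frame], vel=vel[:frame],
        theta=theta[:frame], omega=omega[:frame], box=box, params=params,
    )
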