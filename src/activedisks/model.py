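"""Dimensionless model definition for soft self-propelled disks.

The disks live in a 2D periodic rectangle and interact through a purely
repulsive screened-Coulomb (modified Yukawa) pair potential

    U(r) = Gamma * exp(-kappa * (r - 1)) / r,   truncated at r >= r_c,

in code units where the disk diameter sigma = 1 and the rotational diffusion
time 1/D_r = 1.  The dimensional parameters (m, I, gamma, gamma_r, D_r, sigma,
lambda, U_0, v_0) of the underlying Langevin equations exist only through the
dimensionless groups stored in :class:`SimParams`:

* ``M = (m/gamma) * D_r``      -- reduced translational inertia,
* ``J = (I/gamma_r) * D_r``    -- reduced rotational inertia,
* ``Pe = v_0 / (D_r * sigma)`` -- Peclet number (activity strength),
* ``Gamma = U_0 / (gamma * sigma^3 * D_r)`` -- reduced interaction strength,
* ``kappa = sigma / lambda``   -- softness parameter (hardness grows with it).

The translational equation of motion (no thermal noise) is

    M dv_i/dt = -v_i - grad_i sum_{j<i} U(r_ij) + Pe * n_i,

with self-propulsion direction ``n_i = (cos theta_i, sin theta_i)``; theta_i
follows an inertial rotor driven by white noise (see :mod:`.integrate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._kernels import forces_cell_list

__all__ = [
    "SimParams",
    "Box",
    "ParticleState",
    "minimum_image",
    "wrap_positions",
    "pair_potential",
    "pair_force",
    "total_forces",
    "DEFAULT_ASPECT",
]

#: Default box aspect ratio Lx/Ly commensurate with a triangular lattice.
DEFAULT_ASPECT = 2.0 / math.sqrt(3.0)


@dataclass(frozen=True)
class SimParams:
    """All dimensionless control parameters plus numerical settings.

    Defaults are the production study conditions: global area fraction 0.65,
    interaction strength Gamma = 25, cutoff r_c = 8, time step dt = 1e-4,
    box aspect 2/sqrt(3), N = 48,400 disks.
    """

    M: float = 0.05
    J: float = 2.0
    Pe: float = 125.0
    Gamma: float = 25.0
    kappa: float = 7.0
    phi: float = 0.65
    N: int = 48400
    aspect: float = DEFAULT_ASPECT
    r_c: float = 8.0
    dt: float = 1e-4
    t_end: float = 100.0
    snapshot_every: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        errors = self.validation_errors()
        if errors:
            raise ValueError("invalid SimParams: " + "; ".join(errors))

    def validation_errors(self) -> list[str]:
        errs = []
        if not self.M > 0:
            errs.append(f"M must be > 0 (got {self.M})")
        if not self.J >= 0:
            errs.append(f"J must be >= 0 (got {self.J})")
        if not self.Pe >= 0:
            errs.append(f"Pe must be >= 0 (got {self.Pe})")
        if not self.Gamma > 0:
            errs.append(f"Gamma must be > 0 (got {self.Gamma})")
        if not self.kappa > 0:
            errs.append(f"kappa must be > 0 (got {self.kappa})")
        if not 0 < self.phi < 1:
            errs.append(f"global phi must be in (0, 1) (got {self.phi})")
        if not self.N >= 2:
            errs.append(f"N must be >= 2 (got {self.N})")
        if not self.aspect > 0:
            errs.append(f"aspect must be > 0 (got {self.aspect})")
        if not self.r_c > 1:
            errs.append(f"r_c must be > 1 (got {self.r_c})")
        if not self.dt > 0:
            errs.append(f"dt must be > 0 (got {self.dt})")
        if not self.t_end >= 0:
            errs.append(f"t_end must be >= 0 (got {self.t_end})")
        if not self.snapshot_every > 0:
            errs.append(
                f"snapshot_every must be > 0 (got {self.snapshot_every})"
            )
        return errs

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)

    #: Names, in canonical order, used by config files and snapshot headers.
    FIELD_NAMES = (
        "M", "J", "Pe", "Gamma", "kappa", "phi", "N", "aspect",
        "r_c", "dt", "t_end", "snapshot_every", "seed",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELD_NAMES}


@dataclass(frozen=True)
class Box:
    """Periodic rectangular box with side lengths in units of sigma."""

    Lx: float
    Ly: float

    def __post_init__(self) -> None:
        if not (self.Lx > 0 and self.Ly > 0):
            raise ValueError(f"box sides must be positive: {self.Lx}, {self.Ly}")

    @property
    def area(self) -> float:
        return self.Lx * self.Ly

    @property
    def aspect(self) -> float:
        return self.Lx / self.Ly

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly])

    def phi(self, n: int) -> float:
        """Global area fraction of n unit-diameter disks in this box."""
        return n * math.pi / (4.0 * self.area)


@dataclass
class ParticleState:
    """Positions, velocities, orientations and angular velocities at time t.

    Positions are kept wrapped in [0, Lx) x [0, Ly); theta may be unwrapped
    internally (only cos/sin and differences are ever consumed).
    """

    t: float
    pos: np.ndarray    # (N, 2)
    vel: np.ndarray    # (N, 2)
    theta: np.ndarray  # (N,)
    omega: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        n = self.pos.shape[0]
        if self.pos.shape != (n, 2) or self.vel.shape != (n, 2):
            raise ValueError("pos and vel must both have shape (N, 2)")
        if self.theta.shape != (n,) or self.omega.shape != (n,):
            raise ValueError("theta and omega must have shape (N,)")

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    @property
    def n_hat(self) -> np.ndarray:
        """Self-propulsion directions (cos theta, sin theta), unit by construction."""
        return np.column_stack((np.cos(self.theta), np.sin(self.theta)))

    @property
    def theta_wrapped(self) -> np.ndarray:
        """Orientations wrapped to (-pi, pi]."""
        return np.pi - np.mod(np.pi - self.theta, 2.0 * np.pi)

    def copy(self) -> "ParticleState":
        return ParticleState(
            t=self.t,
            pos=self.pos.copy(),
            vel=self.vel.copy(),
            theta=self.theta.copy(),
            omega=self.omega.copy(),
        )

    def check_finite(self) -> None:
        for name in ("pos", "vel", "theta", "omega"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                bad = int(np.argwhere(~np.isfinite(arr))[0][0])
                raise FloatingPointError(
                    f"non-finite {name} at particle {bad}, t={self.t}"
                )


def minimum_image(dr: np.ndarray, box: Box) -> np.ndarray:
    """Map displacement components into [-L/2, L/2) per dimension. Idempotent."""
    dr = np.asarray(dr, dtype=float)
    L = box.lengths
    return dr - L * np.floor(dr / L + 0.5)


def wrap_positions(pos: np.ndarray, box: Box) -> np.ndarray:
    """Wrap positions into the half-open box [0, Lx) x [0, Ly)."""
    pos = np.asarray(pos, dtype=float)
    L = box.lengths
    return pos - L * np.floor(pos / L)


def pair_potential(r, Gamma: float, kappa: float, r_c: float = 8.0):
    """Truncated (unshifted) modified-Yukawa pair energy.

    U(r) = Gamma * exp(-kappa (r - 1)) / r for r < r_c, else 0.  The ~1e-6
    discontinuity at the default cutoff is documented and deliberate.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    u = np.where(r < r_c, Gamma * np.exp(-kappa * (r - 1.0)) / r, 0.0)
    if u.ndim == 0:
        return float(u)
    return u


def pair_force(dr: np.ndarray, Gamma: float, kappa: float, r_c: float = 8.0) -> np.ndarray:
    """Repulsive force on particle i from j, with dr = r_i - r_j (minimum image).

    Magnitude Gamma * exp(-kappa (r-1)) * (kappa/r + 1/r^2), directed along +dr;
    zero at or beyond the cutoff.
    """
    dr = np.asarray(dr, dtype=float)
    r = float(np.hypot(dr[0], dr[1]))
    if r == 0.0:
        raise FloatingPointError(
            "exact particle overlap (|dr| = 0): broken integration setup"
        )
    if r >= r_c:
        return np.zeros(2)
    mag = Gamma * math.exp(-kappa * (r - 1.0)) * (kappa / r + 1.0 / r**2)
    return (mag / r) * dr


def total_forces(
    positions: np.ndarray,
    box: Box,
    Gamma: float,
    kappa: float,
    r_c: float,
) -> np.ndarray:
    """Conservative forces on all particles via a linked cell list.

    Pair contributions are applied antisymmetrically (Newton's third law), so
    the total momentum input is zero to accumulation tolerance.  Falls back to
    an all-pairs loop when the box holds fewer than 3 cells per dimension.
    Raises on exact overlaps rather than clamping them.
    """
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    forces, overlap = forces_cell_list(
        positions, box.Lx, box.Ly, Gamma, kappa, r_c
    )
    if overlap >= 0:
        raise FloatingPointError(
            f"exact particle overlap involving particle {overlap}"
        )
    return forces
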