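"""Boxes, initial configurations, and synthetic analysis fixtures.

The fixtures (triangular lattices, random gases, prescribed two-phase
slab/disk configurations with chosen velocity and orientation fields) exist so
that every observable in :mod:`.structure` and :mod:`.dynamics` can be tested
against constructions with known answers, without running the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model import Box, ParticleState, SimParams, wrap_positions

__all__ = [
    "make_box",
    "triangular_lattice_init",
    "lattice_constant",
    "FixtureSpec",
    "make_fixture",
    "random_gas_positions",
    "initial_state",
]

_SQ3_2 = math.sqrt(3.0) / 2.0


def make_box(N: int, phi: float, aspect: float) -> Box:
    """Periodic box with area N pi / (4 phi) and Lx/Ly = aspect.

    This inverts the global-area-fraction relation phi = N pi / (4 Lx Ly).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0 < phi < 1.5:
        raise ValueError("phi must be in (0, 1.5)")
    if aspect <= 0:
        raise ValueError("aspect must be > 0")
    area = N * math.pi / (4.0 * phi)
    Ly = math.sqrt(area / aspect)
    return Box(Lx=aspect * Ly, Ly=Ly)


def _lattice_grid(N: int, box: Box) -> tuple[int, int]:
    """Pick (n_x, n_y) with n_x n_y = N tiling the box as close to equilateral
    triangular as possible; even n_y preferred (periodic stagger seam)."""
    best = None
    for nx in range(1, N + 1):
        if N % nx:
            continue
        ny = N // nx
        ratio = (box.Ly / ny) / (box.Lx / nx)  # row spacing / column spacing
        score = abs(ratio / _SQ3_2 - 1.0)
        key = (ny % 2, score)  # even ny sorts first
        if best is None or key < best[0]:
            best = (key, nx, ny)
    (odd, score), nx, ny = best
    if score > 0.05:
        raise ValueError(
            f"N={N} admits no near-triangular tiling of this box "
            f"(best row/column spacing ratio off by {score:.1%})"
        )
    return nx, ny


def lattice_constant(N: int, box: Box) -> float:
    """Nearest-neighbor spacing of the triangular tiling used for N in box."""
    nx, _ = _lattice_grid(N, box)
    return box.Lx / nx


def triangular_lattice_init(
    N: int,
    box: Box,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> np.ndarray:
    """Positions on a periodic triangular lattice filling the box.

    With jitter > 0, each site is displaced uniformly within a disk of radius
    jitter * spacing, so no two particles end up closer than
    (1 - 2 jitter) * spacing.
    """
    nx, ny = _lattice_grid(N, box)
    dx = box.Lx / nx
    dy = box.Ly / ny
    ix = np.arange(nx)
    iy = np.arange(ny)
    X = (ix[None, :] + 0.5 * (iy[:, None] % 2)) * dx
    Y = np.broadcast_to((iy * dy)[:, None], (ny, nx))
    pos = np.column_stack((X.ravel(), Y.ravel()))
    if jitter > 0.0:
        if rng is None:
            raise ValueError("jitter > 0 requires an rng")
        r = jitter * dx * np.sqrt(rng.uniform(0.0, 1.0, N))
        ang = rng.uniform(0.0, 2.0 * np.pi, N)
        pos = pos + np.column_stack((r * np.cos(ang), r * np.sin(ang)))
    return wrap_positions(pos, box)


def random_gas_positions(
    n: int, box: Box, rng: np.random.Generator
) -> np.ndarray:
    return rng.uniform(0.0, 1.0, (n, 2)) * box.lengths


def _triangular_patch(
    n_target: int,
    phi: float,
    box: Box,
    center: np.ndarray,
    inside,
    rng: np.random.Generator,
) -> np.ndarray:
    """Up to n_target triangular-lattice points (packing fraction phi) inside
    the region predicate; the ones closest to `center` are kept."""
    a = math.sqrt(math.pi / (2.0 * math.sqrt(3.0) * phi))
    nx = int(math.ceil(box.Lx / a)) + 2
    ny = int(math.ceil(box.Ly / (a * _SQ3_2))) + 2
    ix = np.arange(nx)
    iy = np.arange(ny)
    X = (ix[None, :] + 0.5 * (iy[:, None] % 2)) * a
    Y = np.broadcast_to((iy * a * _SQ3_2)[:, None], (ny, nx))
    pts = np.column_stack((X.ravel(), Y.ravel()))
    pts = pts[(pts[:, 0] < box.Lx) & (pts[:, 1] < box.Ly)]
    pts = pts[inside(pts)]
    if len(pts) > n_target:
        d2 = np.sum((pts - center) ** 2, axis=1)
        pts = pts[np.argsort(d2)[:n_target]]
    return pts


FixtureKind = Literal[
    "triangular_lattice", "random_gas", "two_phase_slab", "two_phase_disk"
]


@dataclass(frozen=True)
class FixtureSpec:
    """Synthetic configuration recipe.

    For the two-phase kinds, a dense region (triangular packing at phi_dense)
    sits at the box center inside a dilute random gas at phi_dilute; the
    region is a vertical band of width `region_size` (slab) or a disk of
    radius `region_size` (disk).  Velocity fields: 'uniform' (all along
    `direction`), 'random' (i.i.d. directions), 'radial' (outward from the
    box center); all at `speed`.  Orientations follow the velocity direction.
    """

    kind: FixtureKind
    phi: float = 0.65            # target global phi (lattice / gas kinds)
    phi_dense: float = 1.0
    phi_dilute: float = 0.1
    region_size: float | None = None
    velocity: Literal["uniform", "random", "radial"] = "random"
    speed: float = 1.0
    direction: tuple[float, float] = (1.0, 0.0)
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.phi_dense > 1.6:
            raise ValueError(
                f"dense region overfull: phi_dense={self.phi_dense} > 1.6"
            )


def _velocity_field(
    spec: FixtureSpec, pos: np.ndarray, box: Box, rng: np.random.Generator
) -> np.ndarray:
    n = len(pos)
    if spec.velocity == "uniform":
        d = np.asarray(spec.direction, dtype=float)
        d = d / np.hypot(*d)
        return np.tile(spec.speed * d, (n, 1))
    if spec.velocity == "random":
        ang = rng.uniform(-np.pi, np.pi, n)
        return spec.speed * np.column_stack((np.cos(ang), np.sin(ang)))
    if spec.velocity == "radial":
        center = 0.5 * box.lengths
        d = pos - center
        r = np.hypot(d[:, 0], d[:, 1])
        r = np.where(r == 0, 1.0, r)
        return spec.speed * d / r[:, None]
    raise ValueError(f"unknown velocity field {spec.velocity!r}")


def make_fixture(
    spec: FixtureSpec, box: Box, rng: np.random.Generator
) -> ParticleState:
    """Construct a synthetic ParticleState per the fixture recipe.

    Particle counts are integer-rounded from the requested area fractions
    (global phi reproduced within 2%).
    """
    center = 0.5 * box.lengths
    disk_area = math.pi / 4.0

    if spec.kind == "triangular_lattice":
        n = max(2, round(spec.phi * box.area / disk_area))
        nearest = _nearest_tileable(n, box)
        pos = triangular_lattice_init(nearest, box, rng, spec.jitter)
    elif spec.kind == "random_gas":
        n = max(2, round(spec.phi * box.area / disk_area))
        pos = random_gas_positions(n, box, rng)
    elif spec.kind in ("two_phase_slab", "two_phase_disk"):
        if spec.kind == "two_phase_slab":
            w = spec.region_size or 0.4 * box.Lx
            area_dense = w * box.Ly

            def inside(p):
                return np.abs(p[:, 0] - center[0]) <= 0.5 * w
        else:
            radius = spec.region_size or 0.3 * min(box.Lx, box.Ly)
            area_dense = math.pi * radius**2

            def inside(p):
                return np.sum((p - center) ** 2, axis=1) <= radius**2

        n_dense = round(spec.phi_dense * area_dense / disk_area)
        n_dilute = round(
            spec.phi_dilute * (box.area - area_dense) / disk_area
        )
        dense = _triangular_patch(
            n_dense, spec.phi_dense, box, center, inside, rng
        )
        dilute = random_gas_positions(max(n_dilute, 0) + 64, box, rng)
        dilute = dilute[~inside(dilute)][:n_dilute]
        pos = np.vstack((dense, dilute))
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")

    pos = wrap_positions(pos, box)
    vel = _velocity_field(spec, pos, box, rng)
    theta = np.arctan2(vel[:, 1], vel[:, 0])
    omega = np.zeros(len(pos))
    return ParticleState(t=0.0, pos=pos, vel=vel, theta=theta, omega=omega)


def _nearest_tileable(n: int, box: Box) -> int:
    """Largest count <= ~n that admits a near-triangular tiling (2% slack)."""
    for cand in range(n, max(1, n - max(2, n // 50)) - 1, -1):
        try:
            _lattice_grid(cand, box)
            return cand
        except ValueError:
            continue
    raise ValueError(f"no tileable particle count near N={n}")


def initial_state(
    params: SimParams,
    box: Box,
    rng: np.random.Generator,
    jitter: float = 0.05,
    velocity: str = "terminal",
) -> ParticleState:
    """Production initial condition: near-homogeneous jittered triangular
    lattice, uniform random orientations, terminal velocities v = Pe n
    (or zero with velocity='zero'), and angular velocities drawn from the
    stationary distribution Var = 1/J.  Terminal/stationary starts minimize
    transients."""
    pos = triangular_lattice_init(params.N, box, rng, jitter)
    theta = rng.uniform(-np.pi, np.pi, params.N)
    if velocity == "terminal":
        vel = params.Pe * np.column_stack((np.cos(theta), np.sin(theta)))
    elif velocity == "zero":
        vel = np.zeros((params.N, 2))
    else:
        raise ValueError(f"unknown velocity init {velocity!r}")
    if params.J > 0:
        omega = rng.standard_normal(params.N) / math.sqrt(params.J)
    else:
        omega = np.zeros(params.N)
    return ParticleState(t=0.0, pos=pos, vel=vel, theta=theta, omega=omega)
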