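"""Time-dependent observables: retention fraction, velocity/orientation
autocorrelations, effective persistence time, and the spatial velocity
correlation with its fitted strength.

All autocorrelations are averaged over particles and (in steady state) over
sliding time origins.  Velocity statistics use unit vectors; particles with
|v| below 1e-12 at a compared frame are excluded and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .integrate import Trajectory
from .model import Box, minimum_image, wrap_positions

__all__ = [
    "CorrelationCurve",
    "RegionTag",
    "tag_region",
    "retention_fraction",
    "velocity_autocorr",
    "orientation_autocorr",
    "effective_persistence_time",
    "spatial_velocity_corr",
    "CorrFit",
    "fit_corr",
    "correlation_strength",
]

logger = logging.getLogger(__name__)

ZERO_SPEED = 1e-12


@dataclass(frozen=True)
class CorrelationCurve:
    """Binned temporal or spatial correlation (lag in 1/D_r or r in sigma)."""

    abscissa: np.ndarray
    values: np.ndarray
    counts: np.ndarray | None = None


# ------------------------------------------------------------------ regions

@dataclass(frozen=True)
class RegionTag:
    """Particles tagged inside a fixed spatial region at time t1.

    kind 'annulus': distance from `center` in [r_lo, r_hi); kind 'slab':
    |coordinate - center[axis]| along `axis` in [r_lo, r_hi).  The region
    stays fixed in space after tagging; membership later is instantaneous
    (particles may leave and re-enter).
    """

    kind: str
    center: np.ndarray
    r_lo: float
    r_hi: float
    axis: int
    members: np.ndarray
    frame: int
    t1: float

    @property
    def n_tagged(self) -> int:
        return len(self.members)


def _region_distance(
    pos: np.ndarray, center: np.ndarray, box: Box, kind: str, axis: int
) -> np.ndarray:
    d = minimum_image(pos - center, box)
    if kind == "annulus":
        return np.hypot(d[:, 0], d[:, 1])
    if kind == "slab":
        return np.abs(d[:, axis])
    raise ValueError(f"unknown region kind {kind!r}")


def tag_region(
    traj: Trajectory,
    frame: int,
    center: np.ndarray,
    r_lo: float,
    r_hi: float,
    kind: str = "annulus",
    axis: int = 0,
) -> RegionTag:
    """Tag all particles inside the region at the given frame."""
    r = _region_distance(traj.pos[frame], np.asarray(center), traj.box,
                         kind, axis)
    members = np.flatnonzero((r >= r_lo) & (r < r_hi))
    if len(members) == 0:
        raise ValueError("no particles inside the tag region")
    return RegionTag(
        kind=kind, center=np.asarray(center, float), r_lo=r_lo, r_hi=r_hi,
        axis=axis, members=members, frame=frame, t1=float(traj.times[frame]),
    )


def retention_fraction(traj: Trajectory, tag: RegionTag) -> CorrelationCurve:
    """R(t - t1): fraction of tagged particles currently inside the region.

    R(0) = 1; membership is instantaneous, so R may rise again when particles
    re-enter (e.g. through the periodic boundary).
    """
    frames = range(tag.frame, traj.n_frames)
    values = np.empty(len(frames))
    for k, f in enumerate(frames):
        r = _region_distance(
            traj.pos[f][tag.members], tag.center, traj.box, tag.kind, tag.axis
        )
        values[k] = np.mean((r >= tag.r_lo) & (r < tag.r_hi))
    lags = traj.times[tag.frame:] - tag.t1
    return CorrelationCurve(abscissa=lags, values=values)


# ----------------------------------------------------------- autocorrelation

def _origin_indices(traj: Trajectory, t_min: float | None) -> np.ndarray:
    if t_min is None:
        return np.array([0])
    idx = np.flatnonzero(traj.times >= t_min)
    if len(idx) == 0:
        raise ValueError(f"no frames at or after t_min={t_min}")
    return idx


def velocity_autocorr(
    traj: Trajectory, t_min: float | None = None
) -> CorrelationCurve:
    """C_v(t) = < v_hat_i(t0 + t) . v_hat_i(t0) >, averaged over particles
    and (with t_min set) over all time origins t0 >= t_min.  C_v(0) = 1.

    Frames where a particle is slower than 1e-12 are excluded from its
    average (counted in the log)."""
    v = traj.vel
    speed = np.hypot(v[..., 0], v[..., 1])
    ok = speed > ZERO_SPEED
    n_bad = int(ok.size - ok.sum())
    if n_bad:
        logger.info("velocity_autocorr: excluded %d zero-speed samples", n_bad)
    u = np.where(ok[..., None], v / np.maximum(speed, ZERO_SPEED)[..., None], 0.0)
    return _autocorr_from_unit_vectors(traj, u, ok, t_min)


def orientation_autocorr(
    traj: Trajectory, t_min: float | None = None
) -> CorrelationCurve:
    """C_n(t) = < n_i(t0 + t) . n_i(t0) > = < cos(theta(t0+t) - theta(t0)) >."""
    u = np.stack((np.cos(traj.theta), np.sin(traj.theta)), axis=-1)
    ok = np.ones(traj.theta.shape, dtype=bool)
    return _autocorr_from_unit_vectors(traj, u, ok, t_min)


def _autocorr_from_unit_vectors(traj, u, ok, t_min):
    origins = _origin_indices(traj, t_min)
    t_len = traj.n_frames - origins[-1]
    sums = np.zeros(t_len)
    cnts = np.zeros(t_len)
    for o in origins:
        m = min(t_len, traj.n_frames - o)
        dots = np.einsum("tnd,nd->tn", u[o:o + m], u[o])
        valid = ok[o:o + m] & ok[o]
        sums[:m] += np.sum(dots * valid, axis=1)
        cnts[:m] += np.sum(valid, axis=1)
    values = sums / np.maximum(cnts, 1)
    lags = traj.times[origins[-1]:] - traj.times[origins[-1]]
    return CorrelationCurve(abscissa=lags[:t_len], values=values,
                            counts=cnts.astype(int))


def effective_persistence_time(
    curve: CorrelationCurve, threshold: float = 0.01
) -> float:
    """tau_P^e: integral of C_n(t) from 0 to its first crossing below
    `threshold`, plus an exponential-tail correction fitted to the last
    decade of the decay.  Raises if the curve never decays below threshold.
    """
    t = np.asarray(curve.abscissa, float)
    c = np.asarray(curve.values, float)
    below = np.flatnonzero(c < threshold)
    if len(below) == 0:
        raise ValueError(
            f"C_n never decays below {threshold} in the sampled window"
        )
    ic = below[0]
    core = np.trapezoid(c[: ic + 1], t[: ic + 1])
    # exponential tail: rate from the last decade of decay (C in [thr, 10 thr])
    sel = np.flatnonzero((c[: ic + 1] > threshold) & (c[: ic + 1] <= 10 * threshold))
    tail = 0.0
    if len(sel) >= 2:
        slope = np.polyfit(t[sel], np.log(c[sel]), 1)[0]
        if slope < 0:
            tail = c[ic] / (-slope)
    return float(core + tail)


# ------------------------------------------------------- spatial correlation

def spatial_velocity_corr(
    traj: Trajectory,
    frames: np.ndarray | None = None,
    r_max: float | None = None,
    dr: float = 0.1,
    vectors: str = "velocity",
) -> CorrelationCurve:
    """C(r): mean over pairs at distance r of v_hat_i . v_hat_j, averaged
    over the supplied snapshot frames (default: all frames in the trajectory;
    production use follows the 50-frames-spaced-1 convention).

    vectors='orientation' applies the same estimator to the propulsion
    directions n_i instead (used to verify that n carries no spatial
    correlation even when v does)."""
    box = traj.box
    if r_max is None:
        r_max = 0.5 * min(box.Lx, box.Ly)
    if r_max > 0.5 * min(box.Lx, box.Ly):
        raise ValueError("r_max must be <= half the smallest box side")
    if frames is None:
        frames = np.arange(traj.n_frames)
    edges = np.arange(0.0, r_max + dr / 2, dr)
    nb = len(edges) - 1
    sums = np.zeros(nb)
    cnts = np.zeros(nb, dtype=int)
    if vectors not in ("velocity", "orientation"):
        raise ValueError(f"unknown vectors kind {vectors!r}")
    for f in frames:
        pos = wrap_positions(traj.pos[f], box)
        if vectors == "orientation":
            u = np.stack((np.cos(traj.theta[f]), np.sin(traj.theta[f])),
                         axis=-1)
            ok = np.ones(len(u), dtype=bool)
        else:
            v = traj.vel[f]
            speed = np.hypot(v[:, 0], v[:, 1])
            ok = speed > ZERO_SPEED
            u = np.zeros_like(v)
            u[ok] = v[ok] / speed[ok, None]
        tree = cKDTree(pos, boxsize=box.lengths)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if len(pairs) == 0:
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        keep = ok[i] & ok[j]
        i, j = i[keep], j[keep]
        d = minimum_image(pos[i] - pos[j], box)
        r = np.hypot(d[:, 0], d[:, 1])
        dots = np.einsum("pd,pd->p", u[i], u[j])
        which = np.minimum((r / dr).astype(int), nb - 1)
        sums += np.bincount(which, weights=dots, minlength=nb)
        cnts += np.bincount(which, minlength=nb)
    values = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CorrelationCurve(abscissa=centers, values=values, counts=cnts)


# -------------------------------------------------------------------- fits

@dataclass(frozen=True)
class CorrFit:
    """Parameters of the decay model m exp(-a r) / r^b + c."""

    m: float
    a: float
    b: float
    c: float
    residual: float
    converged: bool


def _corr_model(r, m, a, b, c):
    return m * np.exp(-a * r) / r**b + c


def fit_corr(
    curve: CorrelationCurve,
    r_min: float = 0.1,
    r_max: float = 50.0,
) -> CorrFit:
    """Nonlinear least squares of m e^(-a r)/r^b + c to C(r) on [r_min, r_max].

    Multi-start (5 starts over a, b in [0.01, 2]) with best-residual
    selection; a and b constrained non-negative.  If no start converges the
    fit is flagged and callers fall back to integrating the raw curve.
    """
    r = np.asarray(curve.abscissa, float)
    c = np.asarray(curve.values, float)
    keep = (r >= r_min) & (r <= r_max) & np.isfinite(c)
    r, cv = r[keep], c[keep]
    if len(r) < 20:
        raise ValueError("need at least 20 bins inside the fit window")

    c0 = float(cv[-1])
    m0 = float(cv[0] - c0)
    starts = [(0.01, 0.01), (0.1, 0.5), (0.5, 1.0), (1.0, 2.0), (2.0, 0.1)]
    best = None
    for a0, b0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _corr_model, r, cv,
                p0=(m0 if m0 != 0 else 0.1, a0, b0, c0),
                bounds=([-np.inf, 0.0, 0.0, -np.inf],
                        [np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        res = float(np.sum((_corr_model(r, *popt) - cv) ** 2))
        if best is None or res < best[1]:
            best = (popt, res)
    if best is None:
        logger.warning("fit_corr: no start converged; flagging fit")
        return CorrFit(np.nan, np.nan, np.nan, np.nan, np.inf, False)
    (m, a, b, cc), res = best
    return CorrFit(float(m), float(a), float(b), float(cc), res, True)


def correlation_strength(
    fit: CorrFit | None = None,
    curve: CorrelationCurve | None = None,
    r_min: float = 0.1,
    r_max: float = 50.0,
    dr: float = 0.1,
) -> float:
    """S: trapezoidal integral of the fitted C(r) over [0.1, 50], grid 0.1.

    Falls back to interpolating the raw curve when the fit is unavailable or
    flagged as non-converged.
    """
    grid = np.arange(r_min, r_max + dr / 2, dr)
    if fit is not None and fit.converged:
        y = _corr_model(grid, fit.m, fit.a, fit.b, fit.c)
    elif curve is not None:
        good = np.isfinite(curve.values)
        y = np.interp(grid, curve.abscissa[good], curve.values[good])
    else:
        raise ValueError("need a converged fit or a raw curve")
    return float(np.trapezoid(y, grid))
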