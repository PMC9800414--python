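"""Closed-form statistics of the free inertial rotor and the resulting
scaling predictions for the MIPS phase boundary.

The self-propulsion direction obeys J d2(theta)/dt2 = -d(theta)/dt +
sqrt(2) xi(t) (code units, D_r = 1).  With stationary initial angular
velocity the angular mean-square displacement is

    <dtheta^2(t)> = 2 [ t - J (1 - e^(-t/J)) ],

and since the increment is Gaussian the orientation autocorrelation is
C_n(t) = exp(-<dtheta^2>/2).  Its time integral defines the effective
persistence time tau_P^e(J), which interpolates the two printed limits
1 + J (small J) and sqrt(pi J / 2) (large J).  Balancing tau_P^e against the
softness time tau_kappa = 1/kappa yields the phase-boundary scaling
kappa* ~ 1 - J (small J) and kappa* ~ J^(-1/2) (large J); the prefactors
depend on M/Pe and are fitted, not derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "angular_msd_theory",
    "orientation_autocorr_theory",
    "tau_eff_theory",
    "tau_eff_small_J",
    "tau_eff_large_J",
    "softness_time",
    "boundary_kappa",
    "fit_boundary_exponent",
    "J_STAR_DEFAULT",
]

#: Default regime split between the small-J plateau and the J^(-1/2) branch.
J_STAR_DEFAULT = 0.06


def _msd_half(t: float, J: float) -> float:
    """t - J(1 - e^(-t/J)) evaluated stably (series-free via expm1)."""
    if t == 0.0:
        return 0.0
    if J == 0.0:
        return t
    eps = t / J
    return J * (eps + math.expm1(-eps))


def angular_msd_theory(t, J: float):
    """<dtheta^2(t)> = 2 [t - J (1 - e^(-t/J))] for the free rotor with
    stationary initial angular velocity (J >= 0; J = 0 is the overdamped
    limit 2t)."""
    if J < 0:
        raise ValueError("J must be >= 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = 2.0 * np.vectorize(_msd_half)(t_arr, J)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def orientation_autocorr_theory(t, J: float):
    """C_n(t) = exp(-<dtheta^2(t)>/2) (Gaussian angular increment)."""
    return np.exp(-0.5 * np.asarray(angular_msd_theory(t, J)))[()]


def tau_eff_small_J(J: float) -> float:
    """Small-J limit of the effective persistence time: (1 + J)/D_r."""
    return 1.0 + J


def tau_eff_large_J(J: float) -> float:
    """Large-J limit: sqrt(pi J / 2) (= J^(1/2)/D_r^(3/2) up to the
    prefactor carried by the Gaussian integral)."""
    return math.sqrt(math.pi * J / 2.0)


def tau_eff_theory(J: float) -> float:
    """tau_P^e(J) = integral of C_n(t) dt over [0, inf), by adaptive
    quadrature (absolute tail tolerance 1e-10).

    Exactly 1 at J = 0; asymptotically 1 + J for J << 1 and sqrt(pi J/2)
    for J >> 1.
    """
    if J < 0:
        raise ValueError("J must be >= 0")
    if J == 0.0:
        return 1.0

    def f(t):
        return math.exp(-_msd_half(t, J))

    # integrand decays on scale max(1, sqrt(J)); split for quad robustness
    scale = max(1.0, math.sqrt(J), J if J < 1e3 else math.sqrt(J))
    val1, _ = integrate.quad(f, 0.0, 10.0 * scale, limit=400, epsabs=1e-12)
    val2, _ = integrate.quad(f, 10.0 * scale, np.inf, limit=400, epsabs=1e-10)
    return float(val1 + val2)


def softness_time(kappa: float) -> float:
    """tau_kappa = tau_P / kappa = 1/kappa in code units: the deformation
    timescale of soft disks (hard disks: small tau_kappa)."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return 1.0 / kappa


def boundary_kappa(
    J,
    c_small: float = 9.0,
    c_large: float | None = None,
    J_star: float = J_STAR_DEFAULT,
) -> np.ndarray | float:
    """Phase-boundary prediction kappa*(J) from tau_P^e ~ tau_kappa.

    kappa* = c_small (1 - J) for J < J_star and c_large J^(-1/2) for
    J >= J_star.  The prefactors are free (they depend on M/Pe); by default
    c_large is chosen to make the two branches continuous at J_star.
    Above kappa*(J) the system phase separates.
    """
    if c_large is None:
        c_large = c_small * (1.0 - J_star) * math.sqrt(J_star)
    J_arr = np.asarray(J, dtype=float)
    small = c_small * (1.0 - J_arr)
    large = c_large / np.sqrt(np.where(J_arr > 0, J_arr, np.inf))
    out = np.where(J_arr < J_star, small, large)
    return float(out) if J_arr.ndim == 0 else out


@dataclass(frozen=True)
class ScalingFit:
    slope: float
    stderr: float
    intercept: float
    n_points: int


def fit_boundary_exponent(
    J_values: np.ndarray, kappa_star: np.ndarray
) -> ScalingFit:
    """OLS on (log J, log kappa*): regime exponent with standard error.

    Used to check the large-J branch (expected slope -1/2) and the small-J
    plateau (slope ~ 0) against measured boundary points.
    """
    J_values = np.asarray(J_values, float)
    kappa_star = np.asarray(kappa_star, float)
    if len(J_values) < 3:
        raise ValueError("need at least 3 boundary points per regime")
    if np.any(J_values <= 0) or np.any(kappa_star <= 0):
        raise ValueError("J and kappa* must be positive for log-log fit")
    if np.ptp(np.log(J_values)) == 0:
        raise ValueError("degenerate spread in J")
    res = stats.linregress(np.log(J_values), np.log(kappa_star))
    return ScalingFit(
        slope=float(res.slope),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
        n_points=len(J_values),
    )
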