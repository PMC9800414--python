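"""Numba kernels: linked-cell force evaluation and the fused time-step loop.

These are performance plumbing only — the physics they implement is defined in
:mod:`.model` and :mod:`.integrate`, and their correctness is pinned by
all-pairs / per-step reference paths in the test suite.  Everything runs
serially; determinism comes from pre-drawn noise slabs passed in by the caller.

The cell sweep uses a half stencil (self cell plus four forward neighbors) so
every unordered pair is visited exactly once and accumulated antisymmetrically;
periodic wrapping is folded into a precomputed coordinate shift per neighbor
cell, so the inner pair loop has no divisions or branches beyond the cutoff
test.
"""

from __future__ import annotations

import math

import numba
import numpy as np

# Status codes returned by the fused loop.
OK = 0
OVERLAP = 1
NONFINITE = 2


@numba.njit(cache=True, fastmath=True)
def _forces_all_pairs(pos, Lx, Ly, Gamma, kappa, r_c, forces):
    n = pos.shape[0]
    rc2 = r_c * r_c
    pref = Gamma * math.exp(kappa)
    forces[:] = 0.0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dx -= Lx * math.floor(dx / Lx + 0.5)
            dy -= Ly * math.floor(dy / Ly + 0.5)
            r2 = dx * dx + dy * dy
            if r2 < rc2:
                if r2 == 0.0:
                    return i
                r = math.sqrt(r2)
                coef = pref * math.exp(-kappa * r) * (kappa * r + 1.0) / (r2 * r)
                fx = coef * dx
                fy = coef * dy
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[j, 0] -= fx
                forces[j, 1] -= fy
    return -1


@numba.njit(cache=True, fastmath=True)
def _forces_cells(pos, Lx, Ly, Gamma, kappa, r_c, forces,
                  ncx, ncy, counts, starts, fill, order):
    """Half-stencil linked-cell sweep; each unordered pair visited once."""
    n = pos.shape[0]
    rc2 = r_c * r_c
    pref = Gamma * math.exp(kappa)
    ncell = ncx * ncy
    forces[:] = 0.0

    inv_cx = ncx / Lx
    inv_cy = ncy / Ly
    counts[:] = 0
    for i in range(n):
        cx = int(pos[i, 0] * inv_cx)
        cy = int(pos[i, 1] * inv_cy)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        counts[cx + ncx * cy] += 1
    s = 0
    for c in range(ncell):
        starts[c] = s
        s += counts[c]
    starts[ncell] = s
    fill[:] = 0
    for i in range(n):
        cx = int(pos[i, 0] * inv_cx)
        cy = int(pos[i, 1] * inv_cy)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        c = cx + ncx * cy
        order[starts[c] + fill[c]] = i
        fill[c] += 1

    for cy in range(ncy):
        for cx in range(ncx):
            c = cx + ncx * cy
            a0 = starts[c]
            a1 = starts[c + 1]
            # pairs within the cell (no wrap possible)
            for u in range(a0, a1):
                i = order[u]
                xi = pos[i, 0]
                yi = pos[i, 1]
                fxi = 0.0
                fyi = 0.0
                for v in range(u + 1, a1):
                    j = order[v]
                    dx = xi - pos[j, 0]
                    dy = yi - pos[j, 1]
                    r2 = dx * dx + dy * dy
                    if r2 < rc2:
                        if r2 == 0.0:
                            return i
                        r = math.sqrt(r2)
                        coef = (pref * math.exp(-kappa * r)
                                * (kappa * r + 1.0) / (r2 * r))
                        fx = coef * dx
                        fy = coef * dy
                        fxi += fx
                        fyi += fy
                        forces[j, 0] -= fx
                        forces[j, 1] -= fy
                forces[i, 0] += fxi
                forces[i, 1] += fyi
            # four forward neighbor cells, wrap folded into a shift
            for k in range(4):
                if k == 0:
                    ox, oy = 1, 0
                elif k == 1:
                    ox, oy = -1, 1
                elif k == 2:
                    ox, oy = 0, 1
                else:
                    ox, oy = 1, 1
                bx = cx + ox
                by = cy + oy
                sx = 0.0
                sy = 0.0
                if bx >= ncx:
                    bx -= ncx
                    sx = Lx
                elif bx < 0:
                    bx += ncx
                    sx = -Lx
                if by >= ncy:
                    by -= ncy
                    sy = Ly
                b = bx + ncx * by
                b0 = starts[b]
                b1 = starts[b + 1]
                for u in range(a0, a1):
                    i = order[u]
                    xi = pos[i, 0] - sx
                    yi = pos[i, 1] - sy
                    fxi = 0.0
                    fyi = 0.0
                    for v in range(b0, b1):
                        j = order[v]
                        dx = xi - pos[j, 0]
                        dy = yi - pos[j, 1]
                        r2 = dx * dx + dy * dy
                        if r2 < rc2:
                            if r2 == 0.0:
                                return i
                            r = math.sqrt(r2)
                            coef = (pref * math.exp(-kappa * r)
                                    * (kappa * r + 1.0) / (r2 * r))
                            fx = coef * dx
                            fy = coef * dy
                            fxi += fx
                            fyi += fy
                            forces[j, 0] -= fx
                            forces[j, 1] -= fy
                    forces[i, 0] += fxi
                    forces[i, 1] += fyi
    return -1


def forces_cell_list(pos, Lx, Ly, Gamma, kappa, r_c):
    """Dispatch to the cell-list kernel, or all-pairs for boxes < 3 cells/dim.

    Returns (forces, overlap_index); overlap_index is -1 when no exact overlap
    was encountered.
    """
    n = pos.shape[0]
    forces = np.empty((n, 2))
    ncx = int(Lx / r_c)
    ncy = int(Ly / r_c)
    if ncx < 3 or ncy < 3:
        bad = _forces_all_pairs(pos, Lx, Ly, Gamma, kappa, r_c, forces)
    else:
        ncell = ncx * ncy
        counts = np.empty(ncell, dtype=np.int64)
        starts = np.empty(ncell + 1, dtype=np.int64)
        fill = np.empty(ncell, dtype=np.int64)
        order = np.empty(n, dtype=np.int64)
        bad = _forces_cells(pos, Lx, Ly, Gamma, kappa, r_c, forces,
                            ncx, ncy, counts, starts, fill, order)
    return forces, bad


@numba.njit(cache=True, fastmath=True)
def run_chunk(pos, vel, theta, omega, noise,
              Lx, Ly, Gamma, kappa, r_c, Pe,
              em_t, dt,
              j_is_zero, alpha, theta_drift, l11, l21, l22, sqrt2dt):
    """Advance the state in place by noise.shape[0] steps.

    Per step: forces at current positions -> exact-drag translational update
    (using the *current* orientations) -> exact Gaussian rotor update, with
    noise[k, 0, :] and noise[k, 1, :] the two standard-normal slabs of step k.
    Returns (status, particle_index, step_index).
    """
    n = pos.shape[0]
    nsteps = noise.shape[0]
    forces = np.empty((n, 2))
    ncx = int(Lx / r_c)
    ncy = int(Ly / r_c)
    use_cells = ncx >= 3 and ncy >= 3
    if use_cells:
        ncell = ncx * ncy
        counts = np.empty(ncell, dtype=np.int64)
        starts = np.empty(ncell + 1, dtype=np.int64)
        fill = np.empty(ncell, dtype=np.int64)
        order = np.empty(n, dtype=np.int64)
    else:
        counts = np.empty(1, dtype=np.int64)
        starts = np.empty(2, dtype=np.int64)
        fill = np.empty(1, dtype=np.int64)
        order = np.empty(1, dtype=np.int64)

    one_minus_em = 1.0 - em_t
    for k in range(nsteps):
        if use_cells:
            bad = _forces_cells(pos, Lx, Ly, Gamma, kappa, r_c, forces,
                                ncx, ncy, counts, starts, fill, order)
        else:
            bad = _forces_all_pairs(pos, Lx, Ly, Gamma, kappa, r_c, forces)
        if bad >= 0:
            return OVERLAP, bad, k
        for i in range(n):
            fx = forces[i, 0] + Pe * math.cos(theta[i])
            fy = forces[i, 1] + Pe * math.sin(theta[i])
            if not (math.isfinite(fx) and math.isfinite(fy)):
                return NONFINITE, i, k
            vx = vel[i, 0] * em_t + fx * one_minus_em
            vy = vel[i, 1] * em_t + fy * one_minus_em
            vel[i, 0] = vx
            vel[i, 1] = vy
            x = pos[i, 0] + vx * dt
            y = pos[i, 1] + vy * dt
            pos[i, 0] = x - Lx * math.floor(x / Lx)
            pos[i, 1] = y - Ly * math.floor(y / Ly)
        if j_is_zero:
            for i in range(n):
                theta[i] = theta[i] + sqrt2dt * noise[k, 0, i]
        else:
            for i in range(n):
                g1 = noise[k, 0, i]
                g2 = noise[k, 1, i]
                th = theta[i] + theta_drift * omega[i] + l11 * g1
                om = alpha * omega[i] + l21 * g1 + l22 * g2
                theta[i] = th
                omega[i] = om
    return OK, -1, nsteps
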