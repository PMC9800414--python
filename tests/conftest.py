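import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_forces(pos, Lx, Ly, Gamma, kappa, r_c):
    """Independent all-pairs O(N^2) force oracle (pure numpy)."""
    d = pos[:, None, :] - pos[None, :, :]
    L = np.array([Lx, Ly])
    d -= L * np.floor(d / L + 0.5)
    r = np.hypot(d[..., 0], d[..., 1])
    np.fill_diagonal(r, np.inf)
    mag = np.where(
        r < r_c,
        Gamma * np.exp(-kappa * (r - 1.0)) * (kappa / r + 1.0 / r**2),
        0.0,
    )
    return ((mag / r)[..., None] * d).sum(axis=1)


def min_sep_positions(rng, n, Lx, Ly, min_sep=0.7):
    """Rejection-sampled random configuration with a minimum separation."""
    L = np.array([Lx, Ly])
    pts = []
    while len(pts) < n:
        p = rng.uniform(0, 1, 2) * L
        ok = True
        for q in pts:
            d = p - q
            d -= L * np.floor(d / L + 0.5)
            if d @ d < min_sep**2:
                ok = False
                break
        if ok:
            pts.append(p)
    return np.array(pts)
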