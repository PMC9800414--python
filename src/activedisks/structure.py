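"""Static observables of a snapshot: local area fraction, phase labels and
MIPS verdict, hexatic order, radial distribution functions, cluster anatomy,
and the central/peripheral decomposition of the dense phase.

Local area fraction is defined through the periodic Voronoi tessellation,
phi_i = (pi/4) / A_i with A_i the particle's cell area; because soft disks
overlap, phi_i can exceed 1 (dense-phase values around 1.25 are physical).
Phase labels follow the global-threshold rule: a particle is 'dense' iff its
local area fraction strictly exceeds the global one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi, cKDTree

from .model import Box, ParticleState, minimum_image, wrap_positions

__all__ = [
    "voronoi_areas",
    "local_area_fraction",
    "classify_phases",
    "MipsResult",
    "detect_mips",
    "hexatic_order",
    "rdf",
    "first_peak_location",
    "cluster_components",
    "cluster_center",
    "RadialProfile",
    "radial_profile",
    "RegionBounds",
    "region_boundaries",
    "cluster_shape",
    "PhaseReport",
    "phase_report",
]

logger = logging.getLogger(__name__)

DISK_AREA = math.pi / 4.0  # area of a unit-diameter disk


# ----------------------------------------------------------------- Voronoi

def _polygon_area(vertices: np.ndarray) -> float:
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_areas(positions: np.ndarray, box: Box) -> np.ndarray:
    """Periodic Voronoi cell areas; they tile the box (sum = Lx*Ly).

    Periodicity is realized by surrounding the box with the 8 translated
    images (ghost points within a margin for large N) and reading off the
    cells of the core points only.  Degenerate (collinear) inputs are
    perturbed by 1e-9 and retried, with a log record.
    """
    positions = wrap_positions(np.asarray(positions, dtype=float), box)
    n = len(positions)
    if n < 4:
        raise ValueError("Voronoi tessellation needs at least 4 particles")

    spacing = math.sqrt(box.area / n)
    margin = max(6.0 * spacing, 4.0)
    shifts = [
        (ix * box.Lx, iy * box.Ly)
        for ix in (-1, 0, 1)
        for iy in (-1, 0, 1)
        if (ix, iy) != (0, 0)
    ]
    ghosts = []
    for sx, sy in shifts:
        img = positions + (sx, sy)
        if margin < 0.5 * min(box.Lx, box.Ly):
            keep = (
                (img[:, 0] > -margin) & (img[:, 0] < box.Lx + margin)
                & (img[:, 1] > -margin) & (img[:, 1] < box.Ly + margin)
            )
            img = img[keep]
        ghosts.append(img)
    pts = np.vstack([positions] + ghosts)

    try:
        vor = Voronoi(pts)
    except Exception:  # qhull degeneracy (collinear / duplicate inputs)
        logger.warning(
            "degenerate configuration for Voronoi; retrying with 1e-9 jitter"
        )
        jit = np.random.default_rng(0).uniform(-1e-9, 1e-9, pts.shape)
        vor = Voronoi(pts + jit)

    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError(
                f"unbounded Voronoi cell for core particle {i}; "
                "ghost margin too small"
            )
        areas[i] = _polygon_area(vor.vertices[region])
    return areas


def local_area_fraction(positions: np.ndarray, box: Box) -> np.ndarray:
    """Per-particle phi_i = (pi/4) / (Voronoi cell area)."""
    return DISK_AREA / voronoi_areas(positions, box)


# ------------------------------------------------------------ phase labels

def classify_phases(phi_i: np.ndarray, phi_global: float) -> np.ndarray:
    """Boolean labels: True = dense iff phi_i > phi_global (strict)."""
    phi_i = np.asarray(phi_i, dtype=float)
    if not np.all(np.isfinite(phi_i)):
        raise ValueError("phi_i must be finite")
    return phi_i > phi_global


@dataclass(frozen=True)
class MipsResult:
    is_mips: bool
    peaks: np.ndarray          # local-phi locations of detected peaks
    hist: np.ndarray           # smoothed histogram (density)
    bin_centers: np.ndarray


def detect_mips(
    phi_i: np.ndarray,
    bin_width: float = 0.02,
    phi_range: tuple[float, float] = (0.0, 1.6),
    smooth_bins: int = 5,
    prominence_frac: float = 0.05,
    min_separation_bins: int = 5,
) -> MipsResult:
    """Bimodality test on the local-area-fraction distribution.

    The histogram (bin width 0.02 on [0, 1.6]) is smoothed with a moving
    average; phase separation is declared iff at least two local maxima
    survive with prominence >= prominence_frac of the tallest peak and mutual
    separation >= min_separation_bins.
    """
    phi_i = np.asarray(phi_i, dtype=float)
    edges = np.arange(phi_range[0], phi_range[1] + bin_width / 2, bin_width)
    hist, _ = np.histogram(np.clip(phi_i, *phi_range), bins=edges)
    kernel = np.ones(smooth_bins) / smooth_bins
    smoothed = np.convolve(hist.astype(float), kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx, _ = signal.find_peaks(
        smoothed,
        prominence=prominence_frac * smoothed.max(),
        distance=min_separation_bins,
    )
    return MipsResult(
        is_mips=len(idx) >= 2,
        peaks=centers[idx],
        hist=smoothed,
        bin_centers=centers,
    )


# ------------------------------------------------------------ hexatic order

def hexatic_order(positions: np.ndarray, box: Box) -> np.ndarray:
    """Per-particle 6-fold bond-orientational order q6_i.

    q6_i = | (1/6) sum_k exp(i 6 angle_ik) | over the six nearest neighbors
    by minimum-image distance (distance ties broken by particle index);
    angle_ik is the bond angle with the x-axis.  q6_i = 1 on a perfect
    triangular lattice.  Report region averages of this per-particle field.
    """
    positions = wrap_positions(np.asarray(positions, dtype=float), box)
    n = len(positions)
    if n < 7:
        raise ValueError("hexatic order needs at least 7 particles")
    tree = cKDTree(positions, boxsize=box.lengths)
    k = min(n, 13)  # self + extras so distance ties can be re-sorted
    dist, idx = tree.query(positions, k=k)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    # stable tie-break: round distances, then index
    order = np.lexsort((idx, np.round(dist, 9)), axis=1)
    take = order[:, :6]
    rows = np.arange(n)[:, None]
    nbr = idx[rows, take]
    d = minimum_image(positions[nbr] - positions[:, None, :], box)
    ang = np.arctan2(d[..., 1], d[..., 0])
    return np.abs(np.mean(np.exp(6j * ang), axis=1))


# --------------------------------------------------------------------- RDF

@dataclass(frozen=True)
class RadialProfile:
    """Uniformly binned radial (or 1D) observable."""

    bin_centers: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    dr: float


def rdf(
    positions: np.ndarray,
    box: Box,
    r_max: float,
    dr: float = 0.05,
    subset: np.ndarray | None = None,
    subset_area: float | None = None,
) -> RadialProfile:
    """Radial distribution function g(r), optionally restricted to one phase.

    With `subset` (particle indices), only pairs internal to the subset are
    counted and the ideal-gas normalization uses that phase's own number
    density over its own footprint `subset_area` (e.g. the summed Voronoi
    areas of its members), so g -> 1 at large r inside a homogeneous phase.
    """
    positions = wrap_positions(np.asarray(positions, dtype=float), box)
    if r_max > 0.5 * min(box.Lx, box.Ly):
        raise ValueError("r_max must be <= half the smallest box side")
    if subset is not None:
        positions = positions[np.asarray(subset)]
    n = len(positions)
    if n < 2:
        raise ValueError("selected phase has fewer than 2 particles")
    area = box.area if subset_area is None else float(subset_area)
    rho = n / area

    tree = cKDTree(positions, boxsize=box.lengths)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    d = minimum_image(positions[pairs[:, 0]] - positions[pairs[:, 1]], box)
    r = np.hypot(d[:, 0], d[:, 1])
    edges = np.arange(0.0, r_max + dr / 2, dr)
    hist, _ = np.histogram(r, bins=edges)
    shell = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    ideal = 0.5 * n * rho * shell  # pairs counted once
    g = np.where(ideal > 0, hist / ideal, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(bin_centers=centers, values=g, counts=hist, dr=dr)


def first_peak_location(g: RadialProfile) -> float:
    """Radius of the first RDF maximum exceeding g = 1 (inter-particle
    separation proxy), refined by 3-point parabolic interpolation."""
    v = g.values
    for i in range(1, len(v) - 1):
        if v[i] > 1.0 and v[i] >= v[i - 1] and v[i] >= v[i + 1] and v[i] > v[i - 1]:
            denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
            if denom == 0:
                return float(g.bin_centers[i])
            shift = 0.5 * (v[i - 1] - v[i + 1]) / denom
            return float(g.bin_centers[i] + shift * g.dr)
    raise ValueError("g(r) has no interior local maximum above 1")


# ----------------------------------------------------------------- clusters

def cluster_components(
    positions: np.ndarray,
    box: Box,
    labels: np.ndarray,
    r_link: float = 1.2,
) -> list[np.ndarray]:
    """Connected components of dense-labeled particles under minimum-image
    distance <= r_link, sorted by size descending (indices into positions)."""
    if r_link <= 0:
        raise ValueError("r_link must be > 0")
    dense = np.flatnonzero(labels)
    if len(dense) == 0:
        return []
    pts = wrap_positions(positions[dense], box)
    tree = cKDTree(pts, boxsize=box.lengths)
    pairs = tree.query_pairs(r_link, output_type="ndarray")
    m = len(dense)
    if len(pairs) == 0:
        adj = sparse.coo_matrix((m, m))
    else:
        adj = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
    n_comp, comp = connected_components(adj, directed=False)
    clusters = [dense[comp == c] for c in range(n_comp)]
    clusters.sort(key=len, reverse=True)
    return clusters


def cluster_center(
    cluster: np.ndarray, positions: np.ndarray, box: Box
) -> np.ndarray:
    """Wrap-aware (circular-coordinate) mean position of a cluster."""
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    pts = wrap_positions(positions[np.asarray(cluster)], box)
    center = np.empty(2)
    for d, L in enumerate(box.lengths):
        ang = pts[:, d] * (2.0 * math.pi / L)
        mean = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
        center[d] = (mean % (2.0 * math.pi)) * L / (2.0 * math.pi)
    return center


def cluster_shape(
    cluster: np.ndarray,
    positions: np.ndarray,
    box: Box,
    r_link: float = 1.2,
    aspect_threshold: float = 1.5,
) -> tuple[str, float]:
    """Classify the largest cluster as 'circular' or 'slab'.

    A cluster that spans the box in some dimension (detected by full bin
    occupancy at resolution >= r_link) is a slab (the percolating
    'rectangular' morphology); otherwise the gyration-tensor aspect
    sqrt(lambda_max/lambda_min) about the periodic center decides:
    circular iff aspect < aspect_threshold.
    """
    cluster = np.asarray(cluster)
    if len(cluster) < 50:
        raise ValueError("cluster too small to classify (need >= 50)")
    pts = wrap_positions(positions[cluster], box)
    spans = _spans_dimension(pts, box, r_link)
    center = cluster_center(cluster, positions, box)
    d = minimum_image(pts - center, box)
    gyr = d.T @ d / len(d)
    evals = np.linalg.eigvalsh(gyr)
    aspect = math.sqrt(evals[-1] / max(evals[0], 1e-300))
    if spans[0] or spans[1]:
        return "slab", aspect
    return ("circular" if aspect < aspect_threshold else "slab"), aspect


def _spans_dimension(
    pts: np.ndarray, box: Box, r_link: float
) -> tuple[bool, bool]:
    out = []
    for d, L in enumerate(box.lengths):
        nbins = max(1, int(L / r_link))
        occ = np.bincount(
            np.minimum((pts[:, d] / L * nbins).astype(int), nbins - 1),
            minlength=nbins,
        )
        out.append(bool(np.all(occ > 0)))
    return out[0], out[1]


# ------------------------------------------------------ profiles & regions

def radial_profile(
    values: np.ndarray,
    positions: np.ndarray,
    center: np.ndarray,
    box: Box,
    dr: float = 1.0,
    axis: int | None = None,
) -> RadialProfile:
    """Bin means of a per-particle scalar versus distance from `center`.

    axis=None: Euclidean minimum-image distance (circular clusters);
    axis=0/1: |distance| along that coordinate from the mid-line (slabs).
    """
    if dr <= 0:
        raise ValueError("dr must be > 0")
    d = minimum_image(np.asarray(positions, float) - np.asarray(center), box)
    if axis is None:
        r = np.hypot(d[:, 0], d[:, 1])
        r_lim = 0.5 * math.hypot(box.Lx, box.Ly)
    else:
        r = np.abs(d[:, axis])
        r_lim = 0.5 * box.lengths[axis]
    edges = np.arange(0.0, r_lim + dr, dr)
    which = np.digitize(r, edges) - 1
    nb = len(edges) - 1
    counts = np.bincount(which, minlength=nb)[:nb]
    sums = np.bincount(which, weights=values, minlength=nb)[:nb]
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(
        bin_centers=centers, values=means, counts=counts, dr=dr
    )


@dataclass(frozen=True)
class RegionBounds:
    """Central/peripheral decomposition of a dense-phase profile.

    r1: outer edge of the central plateau; r2: radius where the profile has
    decayed into the dilute band; r_p = r2 - r1 is the peripheral width.
    `determinate` is False when no plateau/decay structure exists.
    """

    r1: float
    r2: float
    r_p: float
    plateau: float
    determinate: bool


def region_boundaries(
    profile: RadialProfile,
    dilute_value: float,
    tol: float = 0.05,
    core_frac: float = 0.2,
) -> RegionBounds:
    """Locate the plateau edge r1 and the dilute-decay radius r2.

    The plateau value P is the mean over the innermost `core_frac` of
    occupied bins; r1 is the last radius before the profile leaves the band
    |value - P| <= tol |P - dilute|, and r2 the first radius >= r1 where it
    falls to within tol |P - dilute| of the dilute value.
    """
    occ = np.flatnonzero(profile.counts > 0)
    if len(occ) < 3:
        return RegionBounds(np.nan, np.nan, np.nan, np.nan, False)
    n_core = max(1, int(math.ceil(core_frac * len(occ))))
    plateau = float(np.mean(profile.values[occ[:n_core]]))
    contrast = abs(plateau - dilute_value)
    band = tol * contrast
    if contrast <= 0 or band == 0:
        return RegionBounds(np.nan, np.nan, np.nan, plateau, False)

    r = profile.bin_centers
    v = profile.values
    r1 = None
    for j, i in enumerate(occ):
        if abs(v[i] - plateau) > band:
            if j == 0:
                return RegionBounds(np.nan, np.nan, np.nan, plateau, False)
            r1 = float(r[occ[j - 1]])
            break
    if r1 is None:  # never left the plateau: flat profile
        return RegionBounds(np.nan, np.nan, np.nan, plateau, False)

    sign = 1.0 if plateau > dilute_value else -1.0
    for i in occ:
        if r[i] > r1 and sign * (v[i] - dilute_value) <= band:
            r2 = float(r[i])
            return RegionBounds(r1, r2, r2 - r1, plateau, True)
    return RegionBounds(r1, np.nan, np.nan, plateau, False)


# ------------------------------------------------------------ phase report

@dataclass
class PhaseReport:
    """Aggregated structural verdict for one snapshot."""

    is_mips: bool
    peaks: np.ndarray
    labels: np.ndarray            # True = dense
    phi_i: np.ndarray
    q6_i: np.ndarray
    largest_cluster: np.ndarray
    center: np.ndarray | None
    shape_class: str | None
    gyration_aspect: float | None
    r1: float
    r2: float
    r_p: float
    central_phi: float
    central_q6: float
    central_speed: float
    profile_phi: RadialProfile | None = None
    profile_q6: RadialProfile | None = None
    profile_speed: RadialProfile | None = None

    def as_flat_dict(self) -> dict:
        return {
            "is_mips": self.is_mips,
            "n_peaks": len(self.peaks),
            "peak_locations": " ".join(f"{p:.3f}" for p in self.peaks),
            "n_dense": int(np.sum(self.labels)),
            "largest_cluster_size": len(self.largest_cluster),
            "shape_class": self.shape_class or "",
            "gyration_aspect": self.gyration_aspect or float("nan"),
            "r1": self.r1,
            "r2": self.r2,
            "r_p": self.r_p,
            "central_phi": self.central_phi,
            "central_q6": self.central_q6,
            "central_speed": self.central_speed,
        }


def phase_report(
    state: ParticleState,
    box: Box,
    phi_global: float,
    dr: float = 1.0,
    r_link: float = 1.2,
) -> PhaseReport:
    """Full structural analysis of one snapshot.

    Computes the local-area-fraction field, phase labels and MIPS verdict,
    the largest dense cluster's center and shape, radial (or slab-normal)
    profiles of phi, q6 and speed from the cluster center, and the
    central/peripheral boundaries with central-region means.
    """
    pos = state.pos
    phi_i = local_area_fraction(pos, box)
    q6_i = hexatic_order(pos, box)
    speed = np.hypot(state.vel[:, 0], state.vel[:, 1])
    mips = detect_mips(phi_i)
    labels = classify_phases(phi_i, phi_global)
    clusters = cluster_components(pos, box, labels, r_link)

    nan = float("nan")
    report = PhaseReport(
        is_mips=mips.is_mips, peaks=mips.peaks, labels=labels,
        phi_i=phi_i, q6_i=q6_i,
        largest_cluster=clusters[0] if clusters else np.array([], dtype=int),
        center=None, shape_class=None, gyration_aspect=None,
        r1=nan, r2=nan, r_p=nan,
        central_phi=nan, central_q6=nan, central_speed=nan,
    )
    if len(report.largest_cluster) < 50:
        return report

    cluster = report.largest_cluster
    center = cluster_center(cluster, pos, box)
    shape_class, aspect = cluster_shape(cluster, pos, box, r_link)
    axis = None
    if shape_class == "slab":
        pts = wrap_positions(pos[cluster], box)
        sx, sy = _spans_dimension(pts, box, r_link)
        if sx and not sy:
            axis = 1       # spans x -> profile along the y normal
        elif sy and not sx:
            axis = 0
    prof_phi = radial_profile(phi_i, pos, center, box, dr, axis)
    prof_q6 = radial_profile(q6_i, pos, center, box, dr, axis)
    prof_sp = radial_profile(speed, pos, center, box, dr, axis)
    dilute = (
        float(np.mean(phi_i[~labels])) if np.any(~labels) else 0.0
    )
    bounds = region_boundaries(prof_phi, dilute)

    report.center = center
    report.shape_class = shape_class
    report.gyration_aspect = aspect
    report.profile_phi = prof_phi
    report.profile_q6 = prof_q6
    report.profile_speed = prof_sp
    report.r1, report.r2, report.r_p = bounds.r1, bounds.r2, bounds.r_p
    if bounds.determinate:
        d = minimum_image(pos - center, box)
        rr = np.hypot(d[:, 0], d[:, 1]) if axis is None else np.abs(d[:, axis])
        central = rr <= bounds.r1
        if np.any(central):
            report.central_phi = float(np.mean(phi_i[central]))
            report.central_q6 = float(np.mean(q6_i[central]))
            report.central_speed = float(np.mean(speed[central]))
    return report
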