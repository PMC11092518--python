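"""Spatial firing analysis: rate maps, autocorrelograms, grid metrics.

Conventions follow common MEC practice: 3-cm square bins, Gaussian
smoothing with a 3-cm kernel applied to spike counts and occupancy
separately before division, unvisited bins excluded (NaN) rather than
zero-filled, and the rotational grid score

    score = min(corr at 60, 120 deg) - max(corr at 30, 90, 150 deg)

computed on an annulus around the central autocorrelogram peak and
maximized over the annulus outer radius.  A score of at least 0.2 is
treated as an acceptable grid pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import AnalysisError
from .stimulus import Trajectory

__all__ = [
    "RateMap",
    "Autocorrelogram",
    "GridMetrics",
    "Field",
    "compute_rate_map",
    "spatial_autocorrelogram",
    "grid_score",
    "detect_fields",
    "field_spacing",
    "grid_metrics",
    "GRID_SCORE_THRESHOLD",
]

GRID_SCORE_THRESHOLD = 0.2


@dataclass
class RateMap:
    """Occupancy-normalized firing-rate map.

    ``rate`` is indexed ``[iy, ix]`` with the origin at the arena's
    lower-left corner; unvisited bins are NaN.
    """

    rate: np.ndarray  # spikes/s, NaN where unvisited
    occupancy: np.ndarray  # seconds per bin (unsmoothed)
    bin_cm: float
    smooth_cm: float
    n_spikes: int

    @property
    def visited(self) -> np.ndarray:
        return ~np.isnan(self.rate)

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate))

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted mean rate (equals spikes / time unsmoothed)."""
        occ = self.occupancy
        total = occ.sum()
        return float(np.nansum(np.where(self.visited, self.rate, 0.0) * occ) / total)


@dataclass
class Autocorrelogram:
    """Pearson spatial autocorrelation over 2-D lags (NaN where undefined)."""

    corr: np.ndarray
    bin_cm: float

    @property
    def center(self) -> tuple[int, int]:
        return (self.corr.shape[0] // 2, self.corr.shape[1] // 2)


@dataclass
class Field:
    center_cm: tuple[float, float]
    area_cm2: float
    diameter_cm: float
    peak_rate: float


@dataclass
class GridMetrics:
    score: float
    mean_rate: float
    peak_rate: float
    field_sizes_cm: list[float] = field(default_factory=list)
    spacing_cm: float = float("nan")
    orientation_deg: float = float("nan")

    @property
    def is_grid(self) -> bool:
        return np.isfinite(self.score) and self.score >= GRID_SCORE_THRESHOLD


def compute_rate_map(
    spike_times_s: np.ndarray,
    traj: Trajectory,
    bin_cm: float = 3.0,
    smooth_cm: float = 3.0,
) -> RateMap:
    """Rate map = smoothed spike counts / smoothed occupancy per bin.

    Spike positions are interpolated from the trajectory at spike times.
    Bins the animal never visited stay NaN and are excluded downstream.
    """
    spike_times_s = np.asarray(spike_times_s, dtype=np.float64)
    n_bins = int(np.ceil(traj.arena_cm / bin_cm))
    edges = np.arange(n_bins + 1) * bin_cm

    dt = np.diff(traj.t)
    # Occupancy credited to the bin of the segment's starting sample.
    occ, _, _ = np.histogram2d(traj.y[:-1], traj.x[:-1], bins=(edges, edges), weights=dt)
    if occ.sum() <= 0:
        raise AnalysisError("trajectory has zero total occupancy")

    pos = traj.position_at(spike_times_s) if spike_times_s.size else np.empty((0, 2))
    counts, _, _ = np.histogram2d(pos[:, 1], pos[:, 0], bins=(edges, edges))

    visited = occ > 0
    if smooth_cm > 0:
        sigma = smooth_cm / bin_cm
        sm_counts = ndimage.gaussian_filter(counts, sigma)
        sm_occ = ndimage.gaussian_filter(occ, sigma)
    else:
        sm_counts, sm_occ = counts, occ
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(visited & (sm_occ > 0), sm_counts / np.maximum(sm_occ, 1e-12), np.nan)
    return RateMap(
        rate=rate,
        occupancy=occ,
        bin_cm=bin_cm,
        smooth_cm=smooth_cm,
        n_spikes=int(spike_times_s.size),
    )


def spatial_autocorrelogram(rmap: RateMap, min_overlap: int = 20) -> Autocorrelogram:
    """Pearson correlation of the map with itself at every 2-D lag.

    Only mutually visited bins enter each lag's correlation; lags with
    fewer than ``min_overlap`` overlapping bins (or zero variance) are
    masked NaN.
    """
    z = rmap.rate
    valid = rmap.visited
    if valid.sum() < 2:
        raise AnalysisError("autocorrelogram needs at least two visited bins")
    ny, nx = z.shape
    out = np.full((2 * ny - 1, 2 * nx - 1), np.nan)
    zf = np.where(valid, z, 0.0)
    constant = bool(np.nanstd(z[valid]) == 0)
    if constant:
        warnings.warn("constant rate map: autocorrelogram undefined away from zero lag")
        return Autocorrelogram(corr=out, bin_cm=rmap.bin_cm)
    for dy in range(-(ny - 1), ny):
        ys1 = slice(max(0, dy), min(ny, ny + dy))
        ys2 = slice(max(0, -dy), min(ny, ny - dy))
        for dx in range(-(nx - 1), nx):
            xs1 = slice(max(0, dx), min(nx, nx + dx))
            xs2 = slice(max(0, -dx), min(nx, nx - dx))
            m = valid[ys1, xs1] & valid[ys2, xs2]
            n = int(m.sum())
            if n < min_overlap:
                continue
            a = zf[ys1, xs1][m]
            b = zf[ys2, xs2][m]
            sa = a.std()
            sb = b.std()
            if sa == 0 or sb == 0:
                continue
            out[ny - 1 + dy, nx - 1 + dx] = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
    out[ny - 1, nx - 1] = 1.0
    return Autocorrelogram(corr=out, bin_cm=rmap.bin_cm)


def _radial_profile(ac: Autocorrelogram) -> tuple[np.ndarray, np.ndarray]:
    cy, cx = ac.center
    ys, xs = np.indices(ac.corr.shape)
    r = np.hypot(ys - cy, xs - cx)
    rmax = int(np.floor(r.max()))
    radii = np.arange(1, rmax + 1)
    prof = np.full(radii.size, np.nan)
    for i, rad in enumerate(radii):
        m = (r >= rad - 0.5) & (r < rad + 0.5) & np.isfinite(ac.corr)
        if m.any():
            prof[i] = ac.corr[m].mean()
    return radii, prof


def _central_peak_radius(ac: Autocorrelogram) -> int | None:
    """Radius (bins) of the central peak: first zero crossing of the
    angularly averaged correlation."""
    radii, prof = _radial_profile(ac)
    for rad, val in zip(radii, prof):
        if np.isfinite(val) and val <= 0:
            return int(rad)
    return None


def grid_score(ac: Autocorrelogram) -> float:
    """Rotational grid score, maximized over annulus outer radii.

    Returns NaN when no central peak can be delimited (not a grid).
    """
    r_inner = _central_peak_radius(ac)
    if r_inner is None:
        return float("nan")
    cy, cx = ac.center
    ys, xs = np.indices(ac.corr.shape)
    r = np.hypot(ys - cy, xs - cx)
    filled = np.where(np.isfinite(ac.corr), ac.corr, 0.0)
    finite = np.isfinite(ac.corr)
    rotations = {
        angle: ndimage.rotate(filled, angle, reshape=False, order=1)
        for angle in (30, 60, 90, 120, 150)
    }
    # Only radii whose full ring of lags is defined may enter the annulus;
    # partially masked rings break rotational comparability (the square
    # lag domain would bias 90-degree rotations upward).
    r_max = min(cy, cx)
    ring_ok = np.ones(r_max + 1, dtype=bool)
    for rad in range(1, r_max + 1):
        shell = (r > rad - 0.5) & (r <= rad + 0.5)
        ring_ok[rad] = bool(np.all(finite[shell]))
    best = float("nan")
    for r_outer in range(r_inner + 2, r_max + 1):
        if not np.all(ring_ok[r_inner + 1 : r_outer + 1]):
            break
        ring = (r > r_inner) & (r <= r_outer)
        if ring.sum() < 24:
            continue
        corrs = {}
        for angle, rotated in rotations.items():
            a = filled[ring]
            b = rotated[ring]
            if a.std() == 0 or b.std() == 0:
                corrs[angle] = np.nan
                continue
            corrs[angle] = float(
                np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
            )
        if any(np.isnan(v) for v in corrs.values()):
            continue
        score = min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150])
        if np.isnan(best) or score > best:
            best = score
    return best


def detect_fields(
    rmap: RateMap,
    threshold_frac: float = 0.2,
    min_area_bins: int = 9,
) -> list[Field]:
    """Connected suprathreshold components of the rate map.

    Threshold is a fraction of the map peak; components smaller than
    ``min_area_bins`` bins are discarded, and a component covering more
    than half of the visited area is background firing rather than a
    field (a uniform map therefore has no fields).  Field size is the
    diameter of the circle with the component's area.
    """
    peak = np.nanmax(rmap.rate) if rmap.visited.any() else 0.0
    if not np.isfinite(peak) or peak <= 0:
        return []
    above = np.where(rmap.visited, rmap.rate, 0.0) >= threshold_frac * peak
    labels, n = ndimage.label(above)
    n_visited = int(rmap.visited.sum())
    fields: list[Field] = []
    for lab in range(1, n + 1):
        m = labels == lab
        area_bins = int(m.sum())
        if area_bins < min_area_bins or area_bins > 0.5 * n_visited:
            continue
        area = area_bins * rmap.bin_cm**2
        w = np.where(m, np.nan_to_num(rmap.rate), 0.0)
        cy, cx = ndimage.center_of_mass(w)
        fields.append(
            Field(
                center_cm=((cx + 0.5) * rmap.bin_cm, (cy + 0.5) * rmap.bin_cm),
                area_cm2=area,
                diameter_cm=2.0 * np.sqrt(area / np.pi),
                peak_rate=float(np.nanmax(rmap.rate[m])),
            )
        )
    return sorted(fields, key=lambda f: -f.peak_rate)


def _peripheral_peaks(ac: Autocorrelogram, min_height: float = 0.1) -> np.ndarray:
    """Local autocorrelogram maxima outside the central peak, sorted by
    distance from the center; (n, 2) array of (dy, dx) lags in bins."""
    r_inner = _central_peak_radius(ac)
    if r_inner is None:
        raise AnalysisError("no central autocorrelogram peak: spacing undefined")
    if r_inner < 2:
        # correlation structure confined to a single bin: noise, not fields
        raise AnalysisError("no spatial periodicity beyond the bin scale")
    filled = np.where(np.isfinite(ac.corr), ac.corr, -np.inf)
    maxed = ndimage.maximum_filter(filled, size=3, mode="constant", cval=-np.inf)
    peaks = (filled == maxed) & np.isfinite(ac.corr) & (ac.corr >= min_height)
    cy, cx = ac.center
    ys, xs = np.nonzero(peaks)
    d = np.hypot(ys - cy, xs - cx)
    keep = d > r_inner
    ys, xs, d = ys[keep], xs[keep], d[keep]
    order = np.argsort(d)
    return np.stack([ys[order] - cy, xs[order] - cx], axis=1)


def field_spacing(ac: Autocorrelogram) -> tuple[float, float]:
    """Grid spacing (cm) and orientation (deg) from autocorrelogram peaks.

    Spacing is the median distance from the central peak to its (up to)
    six nearest peripheral peaks; orientation is the angle of the peak
    nearest the horizontal axis, reported modulo 60 degrees.  Raises
    AnalysisError when fewer than three peripheral peaks exist.
    """
    lags = _peripheral_peaks(ac)
    if lags.shape[0] < 3:
        raise AnalysisError("fewer than three peripheral peaks: spacing undefined")
    nearest = lags[:6]
    dist = np.hypot(nearest[:, 0], nearest[:, 1])
    spacing = float(np.median(dist) * ac.bin_cm)
    angles = np.degrees(np.arctan2(nearest[:, 0], nearest[:, 1]))
    horiz = nearest[np.argmin(np.abs(angles))]
    orientation = float(np.degrees(np.arctan2(horiz[0], horiz[1])) % 60.0)
    return spacing, orientation


def spacing_from_field_centers(fields: list[Field]) -> float:
    """Median nearest-neighbor distance between detected field centers (cm).

    The in-box alternative to autocorrelogram spacing: once the grid
    spacing approaches the arena size the six surrounding correlogram
    peaks fall outside the measurable lag range, but distances between
    the rate map's own field centers remain observable.  NaN with fewer
    than two fields.
    """
    if len(fields) < 2:
        return float("nan")
    centers = np.array([f.center_cm for f in fields])
    d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))


def grid_metrics(
    spike_times_s: np.ndarray,
    traj: Trajectory,
    bin_cm: float = 3.0,
    smooth_cm: float = 3.0,
) -> GridMetrics:
    """Convenience pipeline: rate map -> autocorrelogram -> all grid metrics."""
    rmap = compute_rate_map(spike_times_s, traj, bin_cm=bin_cm, smooth_cm=smooth_cm)
    ac = spatial_autocorrelogram(rmap)
    score = grid_score(ac)
    fields = detect_fields(rmap)
    try:
        spacing, orientation = field_spacing(ac)
    except AnalysisError:
        spacing, orientation = spacing_from_field_centers(fields), float("nan")
    return GridMetrics(
        score=score,
        mean_rate=rmap.mean_rate,
        peak_rate=rmap.peak_rate,
        field_sizes_cm=[f.diameter_cm for f in fields],
        spacing_cm=spacing,
        orientation_deg=orientation,
    )
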