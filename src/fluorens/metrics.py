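"""Ensemble descriptors computed from fitted peak tables.

Covers the area-weighted mean chemical shift, the >5%-area major-peak
rule, the bivariate (shift, FWHM) kernel-density cluster map, region area
fractions over a ppm partition, and D₂O solvent-exposure classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import PeakSet


def mean_weighted_shift(peaks: PeakSet, exclude_contaminant: bool = True) -> float:
    """Area-weighted mean chemical shift Σ Aᵢδᵢ / Σ Aᵢ (ppm).

    By default the free-BTFA contaminant is excluded; sub-threshold minor
    peaks are *included* (the >5% rule applies only to the FWHM map).
    """
    ps = peaks.without_contaminants() if exclude_contaminant else peaks
    if len(ps) == 0:
        raise ValueError("empty peak set")
    areas = np.array([p.area for p in ps])
    centers = np.array([p.center for p in ps])
    total = areas.sum()
    if total <= 0:
        raise ValueError("total included peak area must be positive")
    return float(np.dot(areas, centers) / total)


def major_peaks(peaks: PeakSet, min_fraction: float = 0.05) -> PeakSet:
    """Peaks comprising strictly more than ``min_fraction`` of the
    non-contaminant spectrum area."""
    ps = peaks.without_contaminants()
    if len(ps) == 0:
        return PeakSet()
    fracs = ps.area_fractions()
    return PeakSet([p for p, f in zip(ps, fracs) if f > min_fraction])


@dataclass
class ClusterMap:
    """KDE mode clustering of (shift, FWHM) points."""

    points: np.ndarray  # (n, 2): shift ppm, fwhm ppm
    labels: list[str | None]
    density: np.ndarray  # (gx, gy) KDE evaluated on the grid
    grid_x: np.ndarray
    grid_y: np.ndarray
    cluster_labels: np.ndarray  # int per point
    n_clusters: int
    bandwidth: tuple[float, float]
    modes: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def cluster_of(self, label: str) -> int:
        return int(self.cluster_labels[self.labels.index(label)])


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    if sd == 0:
        sd = max(abs(np.mean(x)) * 1e-3, 1e-6)
    return float(sd * n ** (-1.0 / 6.0))  # Silverman/Scott factor for d=2


def cluster_peak_map(
    points: np.ndarray,
    sample_labels: list[str] | None = None,
    bandwidth: tuple[float, float] | None = None,
    grid_size: int = 128,
    floor_fraction: float = 0.05,
    min_persistence: float = 0.25,
) -> ClusterMap:
    """Cluster a (shift, FWHM) scatter by the modes of its Gaussian KDE.

    Density is evaluated on a regular grid with a diagonal (per-dimension)
    bandwidth, Silverman's rule by default. Clusters are the basins of
    attraction of density modes found by a watershed sweep in order of
    decreasing density. Two denoising rules keep the mode set meaningful:

    * modes below ``floor_fraction`` of the global maximum are absorbed
      into the basin they first touch;
    * a mode whose relative prominence — (peak − saddle)/peak at the
      saddle where its basin meets a higher one — is below
      ``min_persistence`` is merged (finite-sample KDE ripples on a single
      cluster otherwise split it spuriously).

    Each point takes the basin label of its nearest grid cell.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (shift, fwhm) points")
    n = pts.shape[0]
    if sample_labels is not None and len(sample_labels) != n:
        raise ValueError("sample_labels must match the number of points")

    if bandwidth is None:
        bw = (_silverman_bandwidth(pts[:, 0]), _silverman_bandwidth(pts[:, 1]))
    else:
        bw = (float(bandwidth[0]), float(bandwidth[1]))
    if min(bw) <= 0:
        raise ValueError("bandwidths must be positive")

    gx = np.linspace(pts[:, 0].min() - 3 * bw[0], pts[:, 0].max() + 3 * bw[0], grid_size)
    gy = np.linspace(pts[:, 1].min() - 3 * bw[1], pts[:, 1].max() + 3 * bw[1], grid_size)
    # separable Gaussian kernels, summed over points
    kx = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / bw[0]) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / bw[1]) ** 2)
    density = (kx @ ky.T) / (n * 2 * np.pi * bw[0] * bw[1])

    basin, peak_height = _watershed_modes(
        density, floor_fraction * density.max(), min_persistence
    )

    # relabel basins 0..k-1 by decreasing peak height
    roots = sorted(set(peak_height), key=lambda r: -peak_height[r])
    relabel = {r: i for i, r in enumerate(roots)}
    labels_arr = np.empty(n, dtype=int)
    for idx, p in enumerate(pts):
        i = int(np.argmin(np.abs(gx - p[0])))
        j = int(np.argmin(np.abs(gy - p[1])))
        labels_arr[idx] = relabel[basin[i, j]]
    mode_coords = []
    for r in roots:
        mi, mj = np.unravel_index(
            np.argmax(np.where(basin == r, density, -np.inf)), density.shape
        )
        mode_coords.append((gx[mi], gy[mj]))

    return ClusterMap(
        points=pts,
        labels=list(sample_labels) if sample_labels is not None else [None] * n,
        density=density,
        grid_x=gx,
        grid_y=gy,
        cluster_labels=labels_arr,
        n_clusters=len(set(labels_arr.tolist())),
        bandwidth=bw,
        modes=np.array(mode_coords),
    )


def _watershed_modes(
    density: np.ndarray, floor: float, min_persistence: float
) -> tuple[np.ndarray, dict[int, float]]:
    """Watershed-by-descending-density with persistence-based mode merging.

    Returns a basin-root id per grid cell and the peak density of each
    surviving basin root.
    """
    shape = density.shape
    order = np.argsort(density.ravel())[::-1]
    basin = np.full(shape, -1, dtype=int)
    parent: dict[int, int] = {}
    peak: dict[int, float] = {}

    def find(r: int) -> int:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    neighbors = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for flat in order:
        i, j = divmod(int(flat), shape[1])
        d = density[i, j]
        touching: list[int] = []
        best_neighbor_root = -1
        best_neighbor_density = -np.inf
        for di, dj in neighbors:
            ni, nj = i + di, j + dj
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and basin[ni, nj] >= 0:
                r = find(basin[ni, nj])
                if r not in touching:
                    touching.append(r)
                if density[ni, nj] > best_neighbor_density:
                    best_neighbor_density = density[ni, nj]
                    best_neighbor_root = r
        if not touching:
            rid = int(flat)
            parent[rid] = rid
            peak[rid] = float(d)
            basin[i, j] = rid
            continue
        # steepest ascent: the cell drains into its highest neighbor's basin
        keep = best_neighbor_root
        basin[i, j] = keep
        # this cell is the saddle between `keep` and every other basin here:
        # merge modes that are sub-floor or insufficiently prominent
        for r in touching:
            if r == keep:
                continue
            prominence = (peak[r] - d) / peak[r] if peak[r] > 0 else 0.0
            if peak[r] < floor or prominence < min_persistence:
                parent[r] = keep
                peak[keep] = max(peak[keep], peak[r])
    # final pass: path-compress basin map
    flat_basin = basin.ravel()
    for idx in range(flat_basin.size):
        flat_basin[idx] = find(flat_basin[idx])
    return basin, {r: peak[r] for r in set(flat_basin.tolist())}


@dataclass(frozen=True)
class RegionPartition:
    """Contiguous ppm regions defined by ordered cut points.

    ``edges`` are ascending ppm values; region i is the half-open interval
    (edges[i], edges[i+1]], so a peak centered exactly on a boundary is
    assigned to the upfield (more negative) region.
    Regions are reported in ascending-ppm order (most upfield first).
    """

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = tuple(float(x) for x in self.edges)
        if len(e) < 3:
            raise ValueError("need at least 3 edges (2 regions)")
        if not all(a < b for a, b in zip(e, e[1:])):
            raise ValueError("edges must be strictly ascending")
        object.__setattr__(self, "edges", e)

    @property
    def n_regions(self) -> int:
        return len(self.edges) - 1

    def region_of(self, center: float) -> int:
        if not (self.edges[0] < center <= self.edges[-1]):
            raise ValueError(f"peak center {center} ppm outside partition window")
        for i in range(self.n_regions):
            if self.edges[i] < center <= self.edges[i + 1]:
                return i
        raise AssertionError("unreachable")


#: Default four-region partition, the two middle regions bracketing the two
#: apo peak positions of the synthetic scenarios (~−83.55 and −83.95 ppm).
DEFAULT_REGIONS = RegionPartition((-86.0, -84.4, -83.75, -83.35, -82.0))


def region_fractions(
    peaks: PeakSet,
    partition: RegionPartition = DEFAULT_REGIONS,
    exclude_contaminant: bool = True,
) -> np.ndarray:
    """Fraction of total included peak area per partition region (sums to 1)."""
    ps = peaks.without_contaminants() if exclude_contaminant else peaks
    if len(ps) == 0:
        raise ValueError("empty peak set")
    out = np.zeros(partition.n_regions)
    for p in ps:
        out[partition.region_of(p.center)] += p.area
    total = out.sum()
    if total <= 0:
        raise ValueError("total included area must be positive")
    return out / total


def d2o_exposure_analysis(
    shifts_by_d2o: np.ndarray,
    exposure_threshold: float = 0.08,
) -> tuple[float, str]:
    """Classify probe solvent exposure from D₂O-dependent shift changes.

    Parameters
    ----------
    shifts_by_d2o : array of (percent D₂O, Δδ ppm) pairs
        Shift changes relative to the lowest-D₂O condition; upfield changes
        are negative (toward more negative ppm).
    exposure_threshold : float
        Minimum |total change| (ppm per 100% D₂O) for a classification other
        than "protected".

    Returns
    -------
    (slope, classification)
        Slope in ppm per 100% D₂O (negative = upfield drift);
        classification ∈ {"solvent-exposed", "protected/interacting",
        "protected"}.
    """
    arr = np.asarray(shifts_by_d2o, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (percent_d2o, delta_ppm) pairs")
    levels = np.unique(arr[:, 0])
    if levels.size < 2:
        raise ValueError("need at least 2 distinct D2O levels")
    fit = stats.linregress(arr[:, 0] / 100.0, arr[:, 1])
    slope = float(fit.slope)  # ppm per 100% D2O
    if slope <= -exposure_threshold:
        return slope, "solvent-exposed"
    if slope >= exposure_threshold:
        return slope, "protected/interacting"
    return slope, "protected"
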