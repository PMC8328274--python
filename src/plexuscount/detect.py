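"""Neuron identification (step 2): local maxima of the smoothed image.

A neuron centroid is a pixel that is maximal over a circular
neighborhood of radius ``delta_m`` and lies in the foreground mask.
``delta_m`` defaults to 2.5 um times the pixel density rho, i.e. no two
somata can sit closer than 2.5 um.  Candidate maxima that fall within
the same delta_m-neighborhood (flat plateaus, near-ties) are merged by
replacing each connected group with the mean of its coordinates,
iterated to a fixed point so that every retained pair of peaks is at
least delta_m apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import ParameterError
from .preprocess import ForegroundMask, IntensityImage

#: Minimum physical separation between somata, in micrometers.
MIN_SEPARATION_UM = 2.5


@dataclass
class PeakSet:
    """Detected neuron centroids for one image.

    ``coordinates`` is an ``(n, 2)`` float array of (row, col) positions,
    0-based and possibly fractional after neighborhood averaging.
    """

    coordinates: np.ndarray
    source_shape: tuple[int, int]
    min_distance_delta_m: float

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64).reshape(-1, 2)

    def __len__(self) -> int:
        return int(self.coordinates.shape[0])


def default_min_distance(rho: float) -> float:
    """Default peak separation delta_m in pixels: 2.5 um x rho."""
    if not (rho > 0):
        raise ParameterError(f"rho must be > 0, got {rho}")
    return MIN_SEPARATION_UM * rho


def _disk_footprint(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (np.hypot(yy, xx) <= radius).astype(bool)


def merge_neighborhood_peaks(raw_peaks, delta_m: float) -> np.ndarray:
    """Average peaks that share a delta_m-neighborhood, to a fixed point.

    Groups are the connected components of the "closer than delta_m"
    graph; each is replaced by its coordinate mean.  Averaging can itself
    move two group means within delta_m of each other, so the merge is
    repeated until the minimum pairwise distance is >= delta_m.  The
    result is sorted in row-major order, making the operation independent
    of the input ordering.
    """
    if not (delta_m >= 1):
        raise ParameterError(f"delta_m must be >= 1 pixel, got {delta_m}")
    pts = np.asarray(raw_peaks, dtype=np.float64).reshape(-1, 2)
    while pts.shape[0] > 1:
        tree = cKDTree(pts)
        pairs = tree.query_pairs(r=delta_m, output_type="ndarray")
        if pairs.size:
            d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
            pairs = pairs[d < delta_m]
        if pairs.size == 0:
            break
        n = pts.shape[0]
        adj = csr_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, comp = connected_components(adj, directed=False)
        merged = np.empty((n_comp, 2), dtype=np.float64)
        for k in range(n_comp):
            merged[k] = pts[comp == k].mean(axis=0)
        pts = merged
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


def detect_peaks(
    smoothed: IntensityImage, mask: ForegroundMask, delta_m: float
) -> PeakSet:
    """All foreground local maxima of a circular delta_m-neighborhood.

    Ties (plateaus of equal maxima) produce several candidate pixels in
    row-major order, which the averaging rule collapses to the plateau
    centroid.  An empty foreground yields an empty PeakSet.
    """
    if smoothed.channels != 1:
        raise ParameterError("detect_peaks expects a single-channel smoothed image")
    if tuple(mask.shape) != smoothed.shape:
        raise ParameterError(
            f"mask shape {mask.shape} does not match image shape {smoothed.shape}"
        )
    if not (delta_m >= 1):
        raise ParameterError(f"delta_m must be >= 1 pixel, got {delta_m}")
    arr = smoothed.pixels.astype(np.float64)
    footprint = _disk_footprint(delta_m)
    local_max = ndi.maximum_filter(arr, footprint=footprint, mode="reflect")
    candidates = np.argwhere((arr >= local_max) & mask.mask)
    merged = merge_neighborhood_peaks(candidates, delta_m)
    return PeakSet(merged, smoothed.shape, float(delta_m))
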