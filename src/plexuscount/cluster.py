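"""Clustering of neuron centroids into ganglia (step 3): DBSCAN.

A ganglion is a density-connected cluster of at least ``Ng = 3`` neurons
whose neighborhood radius is ``eps_m = 20.6 um x rho`` pixels.  DBSCAN
fits this definition naturally: it assumes no preset number of clusters
and leaves sparse points unlabeled, which are exactly the
extraganglionic neurons.  A point's own contribution counts toward the
``min_pts`` core condition, so three mutually close neurons form a
minimal ganglion.

Peaks are fed to DBSCAN in row-major sorted order so that the
(inherently order-dependent) assignment of border points reachable from
two clusters is deterministic and independent of how the peaks were
produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .detect import PeakSet
from .errors import ConsistencyError, ParameterError

#: Label given to neurons that belong to no ganglion (DBSCAN noise).
EXTRAGANGLIONIC = -1

#: Minimum number of neurons in a ganglion (Ng).
DEFAULT_MIN_NEURONS = 3

#: Minimum separation between ganglia, in micrometers.
GANGLION_SEPARATION_UM = 20.6


def default_eps(rho: float) -> float:
    """Default DBSCAN radius eps_m in pixels: 20.6 um x rho."""
    if not (rho > 0):
        raise ParameterError(f"rho must be > 0, got {rho}")
    return GANGLION_SEPARATION_UM * rho


@dataclass
class ClusterLabeling:
    """Per-peak ganglion assignment.

    ``labels[i]`` is a non-negative ganglion id, or :data:`EXTRAGANGLIONIC`
    for a noise point.  Ids are contiguous from 0 in order of first
    appearance along the row-major peak ordering.
    """

    labels: np.ndarray
    eps_m: float
    min_neurons: int = DEFAULT_MIN_NEURONS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_ganglia(self) -> int:
        return int(np.unique(self.labels[self.labels >= 0]).size)

    @property
    def n_extraganglionic(self) -> int:
        return int(np.sum(self.labels == EXTRAGANGLIONIC))

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass
class Ganglion:
    """One cluster of >= Ng neurons with its size and centroid."""

    ganglion_id: int
    member_peaks: np.ndarray
    centroid: tuple[float, float]

    @property
    def size(self) -> int:
        return int(len(self.member_peaks))


def cluster_dbscan(
    peaks: PeakSet, eps: float, min_pts: int = DEFAULT_MIN_NEURONS
) -> ClusterLabeling:
    """Standard DBSCAN on pixel coordinates with Euclidean distance.

    Core points have at least ``min_pts`` points (themselves included)
    within ``eps``; clusters are maximal density-connected sets; the
    rest is extraganglionic.  Empty input yields an empty labeling.
    """
    if not (eps > 0):
        raise ParameterError(f"eps must be > 0, got {eps}")
    if min_pts < 1:
        raise ParameterError(f"min_pts must be >= 1, got {min_pts}")
    n = len(peaks)
    if n == 0:
        return ClusterLabeling(np.empty(0, dtype=np.int64), float(eps), int(min_pts))
    coords = peaks.coordinates
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    sorted_labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords[order])
    labels = np.empty(n, dtype=np.int64)
    labels[order] = sorted_labels
    return ClusterLabeling(labels, float(eps), int(min_pts))


def summarize_clusters(
    labeling: ClusterLabeling, peaks: PeakSet
) -> tuple[list[Ganglion], int]:
    """Tabulate ganglia (id, members, size, centroid) and the noise count."""
    if len(labeling) != len(peaks):
        raise ConsistencyError(
            f"labeling has {len(labeling)} entries but peak set has {len(peaks)}"
        )
    ganglia: list[Ganglion] = []
    for gid in np.unique(labeling.labels[labeling.labels >= 0]):
        members = np.flatnonzero(labeling.labels == gid)
        centroid = peaks.coordinates[members].mean(axis=0)
        ganglia.append(
            Ganglion(int(gid), members, (float(centroid[0]), float(centroid[1])))
        )
    return ganglia, labeling.n_extraganglionic
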