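"""Synthetic micrographs with known neuron positions and ganglia.

The generator emulates the statistical structure the pipeline assumes:
bright soma-like blobs (default soma radius 7 um, i.e. ~14 um diameter,
plausible for murine myenteric neurons) grouped into ganglia of at least
three somata, with intra-ganglion nearest-neighbor spacing below the
clustering radius eps_m and inter-ganglion gaps above
``separation_factor x eps_m``, plus isolated extraganglionic somata, on
a dim background with optional Gaussian pixel noise.  Ganglion sizes
follow the shifted negative binomial NB(r=0.58, p=0.035) + 3 observed
for ileal myenteric ganglia, truncated at ``max_ganglion_size`` so the
requested layout stays placeable.

Everything is driven by a single integer seed (layout and noise use
independent child streams of the same seed), so fixtures are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .cluster import EXTRAGANGLIONIC, ClusterLabeling, default_eps
from .errors import CapacityError, ParameterError
from .detect import PeakSet
from .preprocess import IntensityImage

#: Factor on the soma radius giving the minimum soma-center spacing.
_MIN_SPACING_FACTOR = 2.4

#: Members are placed within this fraction of eps_m of an existing member.
_MAX_SPACING_EPS_FRACTION = 0.9


@dataclass
class FixtureParams:
    """Configuration of one synthetic micrograph.

    Intensities are in 8-bit units by default (``bit_depth=8``); noise is
    independent additive Gaussian with standard deviation ``noise_sd``.
    """

    image_shape: tuple[int, int] = (1200, 1200)
    rho: float = 1.5
    n_ganglia: int = 8
    sizes: Sequence[int] | None = None
    nb_r: float = 0.58
    nb_p: float = 0.035
    max_ganglion_size: int = 60
    n_extraganglionic: int = 5
    soma_radius_um: float = 7.0
    soma_peak_intensity: float = 220.0
    background_intensity: float = 10.0
    noise_sd: float = 0.0
    separation_factor: float = 2.0
    seed: int = 0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if not (self.rho > 0):
            raise ParameterError(f"rho must be > 0, got {self.rho}")
        if not (self.separation_factor > 1):
            raise ParameterError(
                f"separation_factor must be > 1, got {self.separation_factor}"
            )
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.soma_peak_intensity <= self.background_intensity:
            raise ParameterError(
                "soma_peak_intensity must exceed background_intensity"
            )
        if self.bit_depth not in (8, 16):
            raise ParameterError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.sizes is not None and any(s < 3 for s in self.sizes):
            raise ParameterError("every ganglion must have at least 3 neurons")

    @property
    def eps_m(self) -> float:
        return default_eps(self.rho)

    @property
    def soma_radius_px(self) -> float:
        return self.soma_radius_um * self.rho

    def to_dict(self) -> dict:
        return {
            "image_shape": list(self.image_shape),
            "rho": self.rho,
            "n_ganglia": self.n_ganglia,
            "sizes": None if self.sizes is None else list(map(int, self.sizes)),
            "nb_r": self.nb_r,
            "nb_p": self.nb_p,
            "max_ganglion_size": self.max_ganglion_size,
            "n_extraganglionic": self.n_extraganglionic,
            "soma_radius_um": self.soma_radius_um,
            "soma_peak_intensity": self.soma_peak_intensity,
            "background_intensity": self.background_intensity,
            "noise_sd": self.noise_sd,
            "separation_factor": self.separation_factor,
            "seed": self.seed,
            "bit_depth": self.bit_depth,
        }


@dataclass
class SyntheticGroundTruth:
    """Planted neuron positions and their true ganglion memberships."""

    neuron_positions: np.ndarray
    cluster_labels: np.ndarray
    rho: float
    soma_radius_um: float
    image_shape: tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        self.neuron_positions = np.asarray(
            self.neuron_positions, dtype=np.float64
        ).reshape(-1, 2)
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=np.int64)

    @property
    def n_neurons(self) -> int:
        return int(self.neuron_positions.shape[0])

    @property
    def n_ganglia(self) -> int:
        return int(np.unique(self.cluster_labels[self.cluster_labels >= 0]).size)

    @property
    def ganglion_sizes(self) -> list[int]:
        labels = self.cluster_labels[self.cluster_labels >= 0]
        return np.bincount(labels).tolist() if labels.size else []


def _draw_sizes(params: FixtureParams, rng: np.random.Generator) -> np.ndarray:
    if params.sizes is not None:
        if len(params.sizes) != params.n_ganglia:
            raise ParameterError(
                f"{len(params.sizes)} sizes given for {params.n_ganglia} ganglia"
            )
        return np.asarray(params.sizes, dtype=np.int64)
    sizes = np.empty(params.n_ganglia, dtype=np.int64)
    for i in range(params.n_ganglia):
        for _ in range(10_000):
            s = int(rng.negative_binomial(params.nb_r, params.nb_p)) + 3
            if s <= params.max_ganglion_size:
                sizes[i] = s
                break
        else:  # pragma: no cover - would need pathological parameters
            raise CapacityError("could not draw a ganglion size under the cap")
    return sizes


def _place_ganglion(
    size: int,
    center: np.ndarray,
    lo: float,
    hi_r: float,
    hi_c: float,
    min_sp: float,
    max_sp: float,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Grow one ganglion by attaching members near existing ones."""
    members = [center]
    for _ in range(size - 1):
        for _attempt in range(200):
            anchor = members[rng.integers(len(members))]
            ang = rng.uniform(0.0, 2.0 * np.pi)
            dist = rng.uniform(min_sp, max_sp)
            pos = anchor + dist * np.array([np.sin(ang), np.cos(ang)])
            if not (lo <= pos[0] <= hi_r and lo <= pos[1] <= hi_c):
                continue
            d = np.linalg.norm(np.asarray(members) - pos, axis=1)
            if d.min() >= min_sp:
                members.append(pos)
                break
        else:
            return None
    return np.asarray(members)


def sample_layout(params: FixtureParams) -> SyntheticGroundTruth:
    """Place ganglia and extraganglionic somata by rejection sampling.

    Intra-ganglion spacing lies in ``[2.4 x soma_radius, 0.9 x eps_m]``
    pixels (touching-but-resolvable somata, still density-connected);
    every neuron of one ganglion is at least
    ``separation_factor x eps_m`` from every neuron of any other, and
    extraganglionic somata keep the same clearance from everything.  The
    first ganglion is anchored in the central third of the canvas so the
    adaptive threshold region always sees signal.  Placement failure
    after a bounded number of rejections raises :class:`CapacityError`.
    """
    rng = np.random.default_rng([params.seed, 0])
    h, w = params.image_shape
    eps = params.eps_m
    soma_px = params.soma_radius_px
    min_sp = _MIN_SPACING_FACTOR * soma_px
    max_sp = _MAX_SPACING_EPS_FRACTION * eps
    if min_sp >= max_sp:
        raise ParameterError(
            f"soma radius {params.soma_radius_um} um too large for the "
            f"clustering radius: spacing window [{min_sp:.1f}, {max_sp:.1f}] px "
            "is empty"
        )
    margin = soma_px + 2.0
    if h <= 2 * margin or w <= 2 * margin:
        raise CapacityError(f"image {h}x{w} too small for soma radius {soma_px:.1f} px")
    clearance = params.separation_factor * eps
    sizes = _draw_sizes(params, rng)

    positions: list[np.ndarray] = []
    labels: list[int] = []
    placed = np.empty((0, 2))
    for gid, size in enumerate(sizes):
        ok = False
        for _attempt in range(2000):
            if gid == 0:
                center = np.array(
                    [rng.uniform(h / 3, 2 * h / 3), rng.uniform(w / 3, 2 * w / 3)]
                )
                center[0] = min(max(center[0], margin), h - margin)
                center[1] = min(max(center[1], margin), w - margin)
            else:
                center = np.array(
                    [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
                )
            members = _place_ganglion(
                int(size), center, margin, h - margin, w - margin,
                min_sp, max_sp, rng,
            )
            if members is None:
                continue
            if placed.shape[0]:
                d = cKDTree(placed).query(members, k=1)[0]
                if d.min() <= clearance:
                    continue
            positions.extend(members)
            labels.extend([gid] * len(members))
            placed = np.asarray(positions)
            ok = True
            break
        if not ok:
            raise CapacityError(
                f"could not place ganglion {gid} (size {size}) after 2000 "
                "attempts; reduce n_ganglia or enlarge the image"
            )
    for _ in range(params.n_extraganglionic):
        ok = False
        for _attempt in range(2000):
            pos = np.array(
                [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
            )
            if placed.shape[0]:
                d = cKDTree(placed).query(pos[None, :], k=1)[0]
                if d.min() <= clearance:
                    continue
            positions.append(pos)
            labels.append(EXTRAGANGLIONIC)
            placed = np.asarray(positions)
            ok = True
            break
        if not ok:
            raise CapacityError(
                "could not place an extraganglionic neuron after 2000 attempts; "
                "reduce counts or enlarge the image"
            )
    return SyntheticGroundTruth(
        neuron_positions=np.asarray(positions).reshape(-1, 2),
        cluster_labels=np.asarray(labels, dtype=np.int64),
        rho=params.rho,
        soma_radius_um=params.soma_radius_um,
        image_shape=(int(h), int(w)),
        seed=params.seed,
    )


def render_image(gt: SyntheticGroundTruth, params: FixtureParams) -> IntensityImage:
    """Render the ground truth as a noisy grayscale micrograph.

    Each soma is an isotropic Gaussian bump of standard deviation half
    the soma radius (so the half-maximum contour roughly traces the soma
    boundary) and amplitude ``soma_peak - background``; bumps add where
    somata overlap.  Independent Gaussian noise of sd ``noise_sd`` is
    added and the result clipped to the 8- or 16-bit range.
    """
    if tuple(gt.image_shape) != tuple(params.image_shape) or gt.rho != params.rho:
        raise ParameterError("ground truth and params describe different images")
    h, w = params.image_shape
    img = np.full((h, w), float(params.background_intensity), dtype=np.float64)
    amp = params.soma_peak_intensity - params.background_intensity
    sd = params.soma_radius_px / 2.0
    extent = int(np.ceil(4.0 * sd))
    for r, c in gt.neuron_positions:
        r0, r1 = max(int(r) - extent, 0), min(int(r) + extent + 1, h)
        c0, c1 = max(int(c) - extent, 0), min(int(c) + extent + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amp * np.exp(
            -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sd * sd)
        )
    if params.noise_sd > 0:
        noise_rng = np.random.default_rng([params.seed, 1])
        img += noise_rng.normal(0.0, params.noise_sd, size=img.shape)
    vmax = 255 if params.bit_depth == 8 else 65535
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    img = np.clip(np.round(img), 0, vmax).astype(dtype)
    return IntensityImage(img, params.rho)


@dataclass
class DetectionScore:
    """Greedy one-to-one matching of detected peaks to true somata."""

    precision: float | None
    recall: float
    matches: list[tuple[int, int]]  # (peak index, truth index)


def score_detection(
    gt: SyntheticGroundTruth, peaks: PeakSet, tol: float
) -> DetectionScore:
    """Precision/recall of detected peaks against planted positions.

    Candidate (peak, truth) pairs within ``tol`` pixels are matched
    greedily nearest-first, one-to-one.  Precision is missing (``None``)
    when nothing was detected.
    """
    if not (tol > 0):
        raise ParameterError(f"tol must be > 0, got {tol}")
    det = peaks.coordinates
    true = gt.neuron_positions
    candidates: list[tuple[float, int, int]] = []
    if det.shape[0] and true.shape[0]:
        tree = cKDTree(true)
        for i, pos in enumerate(det):
            for j in tree.query_ball_point(pos, tol):
                candidates.append((float(np.linalg.norm(pos - true[j])), i, j))
    candidates.sort()
    used_det: set[int] = set()
    used_true: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_det or j in used_true:
            continue
        used_det.add(i)
        used_true.add(j)
        matches.append((i, j))
    n_det, n_true = det.shape[0], true.shape[0]
    precision = len(matches) / n_det if n_det else None
    recall = len(matches) / n_true if n_true else 0.0
    return DetectionScore(precision=precision, recall=recall, matches=matches)


def score_clustering(
    gt: SyntheticGroundTruth,
    labeling: ClusterLabeling,
    matches: list[tuple[int, int]],
) -> float | None:
    """Pairwise co-clustering agreement over matched neurons, in [0, 1].

    For every pair of matched neurons, truth and prediction agree when
    both place the pair in one common ganglion or both do not (an
    extraganglionic neuron shares a ganglion with nothing).  Fewer than
    two matched neurons make the score undefined (``None``).
    """
    if len(matches) < 2:
        return None
    agree = 0
    total = 0
    for a in range(len(matches)):
        pi, ti = matches[a]
        for b in range(a + 1, len(matches)):
            pj, tj = matches[b]
            true_same = (
                gt.cluster_labels[ti] == gt.cluster_labels[tj]
                and gt.cluster_labels[ti] != EXTRAGANGLIONIC
            )
            pred_same = (
                labeling.labels[pi] == labeling.labels[pj]
                and labeling.labels[pi] != EXTRAGANGLIONIC
            )
            agree += int(true_same == pred_same)
            total += 1
    return agree / total
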