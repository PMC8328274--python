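"""Output segmentation (step 4): watershed flooding and overlays.

The binarized image is flooded with a marker-driven watershed seeded
from the ganglion member peaks (all peaks of one ganglion share a seed
label).  Foreground regions that contain no ganglion peak - debris,
extraganglionic somata - receive no marker and are flooded to
background, so the final label image contains exactly the identified
ganglia.  A colored overlay with one deterministic hue per ganglion is
provided for visual inspection.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from .cluster import ClusterLabeling
from .detect import PeakSet
from .errors import ConsistencyError
from .preprocess import ForegroundMask, IntensityImage

_GOLDEN = 0.6180339887498949


@dataclass
class LabelImage:
    """Integer label raster: 0 = background, k > 0 = ganglion region k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)

    @property
    def n_regions(self) -> int:
        return int(np.unique(self.labels[self.labels > 0]).size)

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]


def watershed_segment(
    mask: ForegroundMask, peaks: PeakSet, labeling: ClusterLabeling
) -> LabelImage:
    """Flood the foreground mask from ganglion-peak seeds.

    Each ganglion's member peaks carry one shared marker label (ganglion
    id + 1); the watershed runs on the negated distance transform of the
    mask, restricted to the mask, so markerless foreground components
    stay background.  Zero ganglia yields an all-background image.
    """
    if len(labeling) != len(peaks):
        raise ConsistencyError(
            f"labeling has {len(labeling)} entries but peak set has {len(peaks)}"
        )
    m = mask.mask
    out = np.zeros(m.shape, dtype=np.int32)
    clustered = labeling.labels >= 0
    if not np.any(clustered):
        return LabelImage(out)
    markers = np.zeros(m.shape, dtype=np.int32)
    h, w = m.shape
    need_snap = False
    seeds = []
    for idx in np.flatnonzero(clustered):
        r = int(np.clip(round(peaks.coordinates[idx, 0]), 0, h - 1))
        c = int(np.clip(round(peaks.coordinates[idx, 1]), 0, w - 1))
        seeds.append((r, c, int(labeling.labels[idx]) + 1))
        if not m[r, c]:
            need_snap = True
    if need_snap:
        _, (ri, ci) = ndi.distance_transform_edt(~m, return_indices=True)
        seeds = [(int(ri[r, c]), int(ci[r, c]), lab) for r, c, lab in seeds]
    for r, c, lab in seeds:
        markers[r, c] = lab
    distance = ndi.distance_transform_edt(m)
    out = watershed(-distance, markers=markers, mask=m).astype(np.int32)
    return LabelImage(out)


def ganglion_color(ganglion_id: int) -> tuple[int, int, int]:
    """Deterministic palette: golden-ratio hue walk seeded by the id."""
    hue = (ganglion_id * _GOLDEN) % 1.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.85, 1.0)
    return int(round(r * 255)), int(round(g * 255)), int(round(b * 255))


def render_overlay(
    img: IntensityImage, label_img: LabelImage, peaks: PeakSet
) -> np.ndarray:
    """RGB uint8 overlay: tinted ganglion regions plus peak markers.

    With no labeled regions and no peaks the grayscale image is simply
    replicated into three channels.
    """
    if label_img.shape != img.shape:
        raise ConsistencyError(
            f"label shape {label_img.shape} does not match image shape {img.shape}"
        )
    gray = img.pixels.astype(np.float64)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    peak_val = float(gray.max()) if gray.size else 0.0
    if peak_val > 255.0:
        gray = gray * (255.0 / peak_val)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    for gid in np.unique(label_img.labels[label_img.labels > 0]):
        color = np.asarray(ganglion_color(int(gid)), dtype=np.float64)
        region = label_img.labels == gid
        rgb[region] = 0.45 * rgb[region] + 0.55 * color
    h, w = img.shape
    for r, c in np.round(peaks.coordinates).astype(int):
        r, c = min(max(r, 0), h - 1), min(max(c, 0), w - 1)
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        rgb[r0:r1, c, :] = (255.0, 255.0, 255.0)
        rgb[r, c0:c1, :] = (255.0, 255.0, 255.0)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)
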