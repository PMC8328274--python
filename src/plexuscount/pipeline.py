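"""End-to-end orchestration of the four processing steps.

``analyze_image`` runs grayscale conversion, Gaussian smoothing,
adaptive thresholding on the center partition, peak detection,
DBSCAN clustering, and (optionally) watershed segmentation on one
image, returning every intermediate product for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cluster import (
    DEFAULT_MIN_NEURONS,
    ClusterLabeling,
    Ganglion,
    cluster_dbscan,
    default_eps,
    summarize_clusters,
)
from .detect import PeakSet, default_min_distance, detect_peaks
from .metrics import PlexusMetrics, compute_metrics, image_area_mm2
from .preprocess import (
    ForegroundMask,
    IntensityImage,
    SmoothingParams,
    binarize,
    center_partition,
    gaussian_smooth,
    otsu_threshold,
    to_grayscale,
)
from .segment import LabelImage, watershed_segment


@dataclass
class PipelineResult:
    """All intermediate and final products of one image analysis."""

    image: IntensityImage
    smoothed: IntensityImage
    mask: ForegroundMask
    peaks: PeakSet
    labeling: ClusterLabeling
    ganglia: list[Ganglion]
    n_extraganglionic: int
    label_image: LabelImage | None
    delta_m: float
    eps_m: float

    @property
    def n_neurons(self) -> int:
        return len(self.peaks)

    @property
    def n_ganglia(self) -> int:
        return len(self.ganglia)

    def metrics(self, area_mm2: float | None = None) -> PlexusMetrics:
        """Plexus metrics over this image; area defaults to the full frame."""
        if area_mm2 is None:
            area_mm2 = image_area_mm2(
                self.image.height, self.image.width, self.image.pixel_density_rho
            )
        return compute_metrics(self.ganglia, self.n_extraganglionic, area_mm2)


def analyze_image(
    img: IntensityImage,
    smoothing: SmoothingParams | None = None,
    delta_m: float | None = None,
    eps_m: float | None = None,
    min_neurons: int = DEFAULT_MIN_NEURONS,
    segment: bool = True,
) -> PipelineResult:
    """Run the full identification / enumeration / clustering pipeline.

    ``delta_m`` and ``eps_m`` default to their physical values
    2.5 um x rho and 20.6 um x rho derived from the image's pixel
    density.  ``segment=False`` skips the watershed output when only
    counts are needed.
    """
    rho = img.pixel_density_rho
    if delta_m is None:
        delta_m = default_min_distance(rho)
    if eps_m is None:
        eps_m = default_eps(rho)
    gray = to_grayscale(img)
    smoothed = gaussian_smooth(gray, smoothing)
    threshold = otsu_threshold(center_partition(smoothed))
    mask = binarize(smoothed, threshold)
    peaks = detect_peaks(smoothed, mask, delta_m)
    labeling = cluster_dbscan(peaks, eps_m, min_neurons)
    ganglia, n_extra = summarize_clusters(labeling, peaks)
    label_image = watershed_segment(mask, peaks, labeling) if segment else None
    return PipelineResult(
        image=img,
        smoothed=smoothed,
        mask=mask,
        peaks=peaks,
        labeling=labeling,
        ganglia=ganglia,
        n_extraganglionic=n_extra,
        label_image=label_image,
        delta_m=float(delta_m),
        eps_m=float(eps_m),
    )
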