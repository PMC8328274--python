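"""Image loading and pre-processing (step 1 of the pipeline).

Micrographs of HuC/D-immunostained myenteric plexus are loaded as-is
(8- or 16-bit TIFF/PNG, grayscale or RGB), converted to a single
grayscale channel, denoised with an isotropic Gaussian filter, and
separated into foreground (neuronal somata) and background (gut wall)
with a threshold chosen adaptively by Otsu's method.  The threshold is
computed on the central region of a 3x3 partition of the image so that
staining artifacts at tissue edges do not bias it, and then applied to
the whole image.

Two user parameters enter here: the pixel density ``rho`` (pixels per
micrometer of the imaging setup, attached to every image) and the
Gaussian smoothing width ``sigma`` (pixels, default 7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, ParameterError, UnsupportedImageError

#: FWHM of a Gaussian = 2 * sqrt(2 * ln 2) * standard deviation.
FWHM_PER_SD = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Rec. 709 luma coefficients used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.2126, 0.7152, 0.0722)

#: Default Gaussian smoothing width in pixels.
DEFAULT_SIGMA = 7.0


@dataclass
class IntensityImage:
    """A 2-D raster of non-negative intensities with pixel-density metadata.

    Parameters
    ----------
    pixels : ndarray
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB array of finite,
        non-negative intensities.  The dtype of the source file is kept
        until processing converts to float.
    pixel_density_rho : float
        Pixels per micrometer of the imaging protocol (> 0).  Scales the
        physical defaults ``delta_m`` and ``eps_m`` downstream.
    """

    pixels: np.ndarray
    pixel_density_rho: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 3 and self.pixels.shape[2] == 1:
            self.pixels = self.pixels[:, :, 0]
        if self.pixels.ndim not in (2, 3):
            raise UnsupportedImageError(
                f"expected a 2-D image, got array of ndim {self.pixels.ndim}"
            )
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise UnsupportedImageError(
                f"expected 1 or 3 channels, got shape {self.pixels.shape}"
            )
        if self.height < 1 or self.width < 1:
            raise ParameterError("image must contain at least one pixel")
        if not (self.pixel_density_rho > 0):
            raise ParameterError(
                f"pixel_density_rho must be > 0, got {self.pixel_density_rho}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("image intensities must be finite")
        if np.any(self.pixels < 0):
            raise ParameterError("image intensities must be non-negative")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else int(self.pixels.shape[2])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def with_pixels(self, pixels: np.ndarray) -> "IntensityImage":
        """New image with the same metadata but different pixel data."""
        return IntensityImage(pixels, self.pixel_density_rho)


@dataclass
class ForegroundMask:
    """Boolean foreground/background mask plus the threshold that made it.

    Foreground is defined by the strict comparison ``intensity > threshold``.
    """

    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]


@dataclass
class SmoothingParams:
    """Gaussian smoothing configuration.

    ``sigma`` is in pixels.  With ``interpretation="sd"`` (default) it is
    used directly as the kernel standard deviation; with ``"fwhm"`` it is
    read as a full width at half maximum and divided by 2.3548.
    """

    sigma: float = DEFAULT_SIGMA
    interpretation: str = "sd"

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.interpretation not in ("sd", "fwhm"):
            raise ParameterError(
                f"interpretation must be 'sd' or 'fwhm', got {self.interpretation!r}"
            )

    @property
    def sd(self) -> float:
        """Kernel standard deviation in pixels."""
        if self.interpretation == "fwhm":
            return self.sigma / FWHM_PER_SD
        return self.sigma


def load_image(path, pixel_density_rho: float) -> IntensityImage:
    """Read a TIFF or PNG micrograph from ``path``.

    Bit depth is preserved as stored.  Multi-channel images beyond RGB
    and Z-stacks are rejected: the pipeline operates on 2-D data only.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any decoder failure
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise UnsupportedImageError(
            f"{path!r}: expected grayscale or RGB, got shape {arr.shape} "
            "(Z-stacks and >3-channel images are not supported)"
        )
    if arr.ndim not in (2, 3):
        raise UnsupportedImageError(
            f"{path!r}: expected 2-D image data, got shape {arr.shape}"
        )
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ParameterError(
            f"{path!r}: micrograph must be at least 3x3 pixels for the "
            f"3x3 threshold partition, got {arr.shape[0]}x{arr.shape[1]}"
        )
    return IntensityImage(arr, pixel_density_rho)


def to_grayscale(img: IntensityImage) -> IntensityImage:
    """Collapse RGB to one channel with Rec. 709 luma weights.

    Single-channel input is passed through unchanged (same dtype); RGB
    input yields float64 ``0.2126 R + 0.7152 G + 0.0722 B``.
    """
    if img.channels == 1:
        return img
    w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
    gray = img.pixels.astype(np.float64) @ w
    return img.with_pixels(gray)


def gaussian_smooth(
    img: IntensityImage, params: SmoothingParams | None = None
) -> IntensityImage:
    """Convolve with an isotropic Gaussian kernel (reflect boundary).

    Reflection at the borders avoids the dark frame that zero padding
    would imprint on stitched-mosaic edges.  Output is float64.
    """
    from scipy import ndimage as ndi

    if params is None:
        params = SmoothingParams()
    if img.channels != 1:
        raise ParameterError("gaussian_smooth expects a single-channel image")
    smoothed = ndi.gaussian_filter(
        img.pixels.astype(np.float64), sigma=params.sd, mode="reflect"
    )
    return img.with_pixels(smoothed)


def center_partition(img: IntensityImage) -> IntensityImage:
    """Return the central region of a 3x3 equal partition of the image.

    For a dimension ``d`` the central band is ``[floor(d/3), floor(2d/3))``,
    a fixed convention when ``d`` is not divisible by three.
    """
    h, w = img.height, img.width
    if h < 3 or w < 3:
        raise ParameterError(f"image must be at least 3x3 to partition, got {h}x{w}")
    r0, r1 = h // 3, (2 * h) // 3
    c0, c1 = w // 3, (2 * w) // 3
    return img.with_pixels(img.pixels[r0:r1, c0:c1])


def otsu_threshold(region: IntensityImage) -> float:
    """Otsu's threshold of a region: minimizes within-class intensity variance.

    8-bit integer data is thresholded on its exact 256-level histogram.
    Wider or floating-point data is min-max scaled onto a 256-bin
    histogram and the selected threshold mapped back, so behaviour is
    uniform across 8- and 16-bit sources.
    """
    arr = region.pixels if isinstance(region, IntensityImage) else np.asarray(region)
    if arr.ndim != 2:
        raise ParameterError("otsu_threshold expects a single-channel region")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        raise DegenerateInputError(
            "region is constant; no foreground/background separation exists "
            "(tissue edge with no signal?) - supply a region containing tissue"
        )
    if arr.dtype == np.uint8:
        return float(threshold_otsu(arr, nbins=256))
    scaled = (arr.astype(np.float64) - lo) * (255.0 / (hi - lo))
    t = float(threshold_otsu(scaled, nbins=256))
    return lo + t * (hi - lo) / 255.0


def binarize(img: IntensityImage, threshold: float) -> ForegroundMask:
    """Foreground mask of pixels strictly above ``threshold``."""
    if img.channels != 1:
        raise ParameterError("binarize expects a single-channel image")
    return ForegroundMask(img.pixels > threshold, float(threshold))
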