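"""Plexus-level structural metrics.

Given the per-image ganglia tables this module computes the summary
statistics used to describe myenteric-plexus organization: neuronal and
ganglionic density (per mm^2 of imaged tissue), mean ganglion size, the
ganglia-size frequency histogram in bins of three neurons, a shifted
negative-binomial model of the size distribution, and the ordinary
least-squares concordance between automated and manual counts.

The size model is NB(r, p) on ``k = size - 3``: since a ganglion has at
least three neurons by definition, the excess over three is the natural
count variable.  Its pmf is ``C(k + r - 1, k) p^r (1 - p)^k`` with mean
``r (1 - p) / p``, fitted by maximum likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConsistencyError, FitError, ParameterError

#: Ganglion sizes are binned in increments of three neurons.
DEFAULT_BIN_WIDTH = 3

#: Minimum neurons per ganglion; also the shift of the size model.
SIZE_SHIFT = 3


@dataclass
class PlexusMetrics:
    """Per-tissue structural summary."""

    n_neurons: int
    n_ganglia: int
    n_extraganglionic: int
    area_mm2: float
    neuronal_density: float
    ganglionic_density: float
    ganglia_sizes: list[int] = field(default_factory=list)
    mean_ganglion_size: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_neurons": self.n_neurons,
            "n_ganglia": self.n_ganglia,
            "n_extraganglionic": self.n_extraganglionic,
            "area_mm2": self.area_mm2,
            "neuronal_density_per_mm2": self.neuronal_density,
            "ganglionic_density_per_mm2": self.ganglionic_density,
            "mean_ganglion_size": self.mean_ganglion_size,
        }

    def summary(self) -> str:
        mean = (
            f"{self.mean_ganglion_size:.2f}"
            if self.mean_ganglion_size is not None
            else "n/a"
        )
        return (
            f"neurons: {self.n_neurons} ({self.n_extraganglionic} extraganglionic)\n"
            f"ganglia: {self.n_ganglia}\n"
            f"area: {self.area_mm2:.2f} mm^2\n"
            f"neuronal density: {self.neuronal_density:.2f} neurons/mm^2\n"
            f"ganglionic density: {self.ganglionic_density:.2f} ganglia/mm^2\n"
            f"mean ganglion size: {mean} neurons/ganglion"
        )


@dataclass
class NBFit:
    """Maximum-likelihood shifted negative-binomial fit of ganglion sizes."""

    r: float
    p: float
    shift: int
    log_likelihood: float

    @property
    def mean_size(self) -> float:
        """Model mean ganglion size: r (1 - p) / p + shift."""
        return self.r * (1.0 - self.p) / self.p + self.shift


@dataclass
class ConcordanceFit:
    """OLS fit of automated counts against manual counts."""

    slope: float
    intercept: float
    r_squared: float


def image_area_mm2(height: int, width: int, rho: float) -> float:
    """Imaged area in mm^2 for a height x width raster at rho pixels/um."""
    if not (height > 0 and width > 0 and rho > 0):
        raise ParameterError(
            f"height, width, rho must be positive, got {height}, {width}, {rho}"
        )
    return (height / rho) * (width / rho) / 1.0e6


def compute_metrics(
    ganglia, n_extraganglionic: int, area_mm2: float
) -> PlexusMetrics:
    """Densities and size statistics from a ganglia table.

    ``ganglia`` is a list of :class:`~plexuscount.cluster.Ganglion`
    objects or of plain integer sizes.  Extraganglionic neurons count
    toward the neuron total and neuronal density but are excluded from
    every ganglia statistic.  With zero ganglia the densities are zero
    and the mean size is missing.
    """
    if not (area_mm2 > 0):
        raise ParameterError(f"area_mm2 must be > 0, got {area_mm2}")
    if n_extraganglionic < 0:
        raise ParameterError("n_extraganglionic must be >= 0")
    sizes = [int(g) if isinstance(g, (int, np.integer)) else g.size for g in ganglia]
    n_ganglia = len(sizes)
    n_neurons = int(sum(sizes) + n_extraganglionic)
    return PlexusMetrics(
        n_neurons=n_neurons,
        n_ganglia=n_ganglia,
        n_extraganglionic=int(n_extraganglionic),
        area_mm2=float(area_mm2),
        neuronal_density=n_neurons / area_mm2,
        ganglionic_density=n_ganglia / area_mm2,
        ganglia_sizes=sizes,
        mean_ganglion_size=(sum(sizes) / n_ganglia) if n_ganglia > 0 else None,
    )


def size_histogram(
    ganglia_sizes, bin_width: int = DEFAULT_BIN_WIDTH
) -> pd.DataFrame:
    """Frequency table of ganglion sizes in contiguous bins from size 3.

    Bins are [3, 5], [6, 8], ... for the default width of three; the
    frequencies sum to the number of ganglia.
    """
    if bin_width < 1:
        raise ParameterError(f"bin_width must be >= 1, got {bin_width}")
    sizes = np.asarray(list(ganglia_sizes), dtype=np.int64)
    if sizes.size == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "frequency"]).astype(
            {"bin_start": np.int64, "bin_end": np.int64, "frequency": np.int64}
        )
    if sizes.min() < SIZE_SHIFT:
        raise ConsistencyError(
            f"ganglion sizes must be >= {SIZE_SHIFT}, got {sizes.min()}"
        )
    idx = (sizes - SIZE_SHIFT) // bin_width
    counts = np.bincount(idx)
    starts = SIZE_SHIFT + bin_width * np.arange(counts.size)
    return pd.DataFrame(
        {
            "bin_start": starts,
            "bin_end": starts + bin_width - 1,
            "frequency": counts,
        }
    )


def nb_log_likelihood(sizes, r: float, p: float, shift: int = SIZE_SHIFT) -> float:
    """Log-likelihood of shifted-NB(r, p) at the given ganglion sizes."""
    k = np.asarray(list(sizes), dtype=np.int64) - shift
    return float(stats.nbinom.logpmf(k, r, p).sum())


def fit_shifted_negative_binomial(
    ganglia_sizes, shift: int = SIZE_SHIFT
) -> NBFit:
    """Maximum-likelihood NB fit to ganglion sizes minus ``shift``.

    The likelihood is profiled: at the optimum the model mean matches the
    sample mean, so ``p = r / (r + mean)`` and only ``log r`` is searched
    (bounded scalar minimization, deterministic).  Raw sizes are fitted,
    not the width-3 histogram, which is only a visualization.
    """
    sizes = np.asarray(list(ganglia_sizes), dtype=np.int64)
    if sizes.size < 2:
        raise FitError(f"need at least 2 ganglion sizes to fit, got {sizes.size}")
    k = sizes - shift
    if k.min() < 0:
        raise ConsistencyError(
            f"all sizes must be >= shift ({shift}), got min {sizes.min()}"
        )
    mean = float(k.mean())
    if np.all(k == k[0]) or mean == 0.0:
        raise FitError(
            "degenerate size distribution (zero variance); cannot fit a "
            "negative binomial"
        )

    def negloglik(log_r: float) -> float:
        r = math.exp(log_r)
        p = r / (r + mean)
        return -float(stats.nbinom.logpmf(k, r, p).sum())

    res = optimize.minimize_scalar(
        negloglik,
        bounds=(math.log(1e-6), math.log(1e6)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    r_hat = float(math.exp(res.x))
    p_hat = r_hat / (r_hat + mean)
    return NBFit(r=r_hat, p=p_hat, shift=shift, log_likelihood=-float(res.fun))


def concordance_regression(auto_counts, manual_counts) -> ConcordanceFit:
    """OLS of automated counts on manual counts: auto = slope * manual + b."""
    auto = np.asarray(list(auto_counts), dtype=np.float64)
    manual = np.asarray(list(manual_counts), dtype=np.float64)
    if auto.size != manual.size:
        raise ConsistencyError(
            f"paired lists differ in length: {auto.size} vs {manual.size}"
        )
    if auto.size < 3:
        raise FitError(f"need at least 3 pairs, got {auto.size}")
    if np.ptp(manual) == 0:
        raise FitError("manual counts have zero variance; slope is undefined")
    res = stats.linregress(manual, auto)
    return ConcordanceFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )
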