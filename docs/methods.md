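# Methods

## Problem and model

Wholemount preparations of the gut's longitudinal muscle–myenteric plexus,
immunostained for the pan-neuronal marker HuC/D, show neuronal somata as bright
blobs grouped into ganglia on a dim tissue background. `plexuscount` turns such
a 2-D widefield micrograph into (i) a set of neuron centroids, (ii) a partition
of those centroids into ganglia plus an "extraganglionic" remainder, and
(iii) tissue-level structural metrics. The processing is a fixed four-step
sequence:

1. **Pre-processing.** RGB is collapsed to one channel (Rec. 709 luma weights),
   smoothed with an isotropic Gaussian filter, and thresholded. The threshold
   is Otsu's minimum-intraclass-variance value computed on the *center* region
   of a 3×3 partition of the image — the center is used because tissue edges of
   stitched mosaics often carry staining artifacts that would bias a global
   histogram — and then applied to the whole image.
2. **Neuron identification.** Neuron centroids are the local maxima of the
   smoothed image over a circular neighborhood of radius δm, restricted to
   foreground. Candidate maxima that fall inside one another's δm-neighborhood
   (plateau ties, near-coincident maxima) are replaced by the mean of their
   coordinates, iterated to a fixed point, so retained peaks are pairwise
   ≥ δm apart.
3. **Clustering into ganglia.** DBSCAN on the centroid coordinates with radius
   εm and minimum cluster size Ng. DBSCAN needs no preset cluster count and
   labels sparse points as noise — exactly the extraganglionic neurons. A
   point counts toward its own neighborhood, so Ng = 3 means three mutually
   close neurons already form a ganglion.
4. **Output segmentation.** A marker-driven watershed on the negated distance
   transform of the binary mask, seeded with one shared label per ganglion
   (at its member peaks) and restricted to the mask, floods the foreground.
   Foreground components holding no ganglion peak stay background, so the
   label image contains exactly the identified ganglia. An RGB overlay tints
   each ganglion with a deterministic golden-ratio hue keyed to its id.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| ρ (`rho`) | pixels/μm | required | pixel density of the imaging setup |
| σ (`sigma`) | pixels | 7 | Gaussian smoothing width |
| `sigma_interpretation` | — | `"sd"` | whether σ is the kernel SD or a FWHM |
| δm (`delta_m`) | pixels | 2.5 μm × ρ | minimum separation of detected somata |
| εm (`eps_m`) | pixels | 20.6 μm × ρ | DBSCAN radius = minimum ganglion separation |
| Ng (`min_neurons`) | neurons | 3 | minimum neurons per ganglion |

δm and εm are physical lengths (2.5 μm ≈ a conservative lower bound on
soma-center separation; 20.6 μm the operational minimum gap between distinct
ganglia) converted to pixels by ρ, and both can be overridden for other
imaging protocols. σ = 7 px is passed directly as the kernel standard
deviation by default; the `"fwhm"` flag divides by 2√(2 ln 2) ≈ 2.3548 for
users who prefer to read σ as a full width at half maximum. Both readings are
exposed because the two conventions differ by a factor ≈ 2.35 and either may
match a given acquisition pipeline; the default was chosen once and is used
throughout.

Numerical conventions, fixed and tested: foreground is *strictly* above the
threshold; the 3×3 partition uses floor boundaries (`[⌊d/3⌋, ⌊2d/3⌋)`);
convolution uses reflective boundaries (no dark frame at mosaic edges);
images are processed in float64 regardless of input depth, with Otsu computed
on the exact 256-level histogram for 8-bit data and on a min–max-scaled
256-bin histogram for wider or floating-point data; DBSCAN border points are
made deterministic by feeding peaks in row-major order; peak merging uses
connected components of the "closer than δm" graph (the only
order-independent grouping) iterated to a fixed point.

## Structural metrics

Neuronal and ganglionic densities are counts divided by imaged area,
`(H/ρ)(W/ρ)/10⁶` mm² by default or a user-supplied tissue area.
Extraganglionic neurons are included in neuron counts and neuronal density
but excluded from all ganglia statistics. Ganglion sizes are histogrammed in
bins of three neurons starting at size 3 and modelled as a shifted negative
binomial: for size X, `X − 3 ~ NB(r, p)` with pmf
`C(k+r−1, k) p^r (1−p)^k`. The fit is maximum likelihood on the raw shifted
sizes (the histogram is presentation only), profiled to one dimension via the
MLE identity `p = r/(r + mean)` and solved by bounded scalar minimization
over log r — deterministic, no starting-point sensitivity. Reference
parameters for healthy murine ileum are (r, p) ≈ (0.58, 0.035), implying a
mean ganglion size of r(1−p)/p + 3 ≈ 19 neurons. Concordance between
automated and manual counts is summarized by simple OLS
(`auto = slope · manual + intercept`) with its r².

## Synthetic fixtures

The generator plants ganglia whose sizes are drawn from the shifted
NB(0.58, 0.035) law (or are given explicitly), grows each ganglion by
attaching somata at 2.4–0.9·εm/soma-radius spacing so intra-ganglion
nearest-neighbor distances stay below εm while somata never overlap, and
rejects any placement whose minimum gap to other ganglia or extraganglionic
somata is below `separation_factor × εm`. Somata are rendered as Gaussian
bumps of SD half the soma radius (default soma radius 7 μm, a realistic
murine myenteric soma half-diameter) on a uniform background, with optional
additive Gaussian noise; a single seed drives independent layout and noise
streams, so fixtures are bit-reproducible. One ganglion is always anchored
in the central third of the canvas so the adaptive-threshold region contains
signal, mimicking a field of view centered on tissue. NB draws are truncated
at `max_ganglion_size` (default 60) because an unbounded heavy tail can
request ganglia that physically cannot fit the canvas; the generator raises
a capacity error rather than silently relaxing its spacing guarantees.

What the fixtures deliberately do **not** emulate: non-uniform illumination,
fiber tracts and glia, anisotropic or lobulated ganglion shapes, staining
gradients, soma size variation, and tissue folds. Exact end-to-end recovery
on these fixtures therefore demonstrates the correctness of the
implementation under the model's own assumptions — clean, well-separated,
homogeneously stained somata — not performance on degraded real tissue,
where accuracy depends on staining and imaging quality.

Scoring: detected peaks are matched one-to-one to planted positions greedily
nearest-first within a tolerance; precision = matched/detected,
recall = matched/planted. Clustering is scored as the fraction of matched
neuron pairs whose co-membership (same ganglion vs not, with extraganglionic
sharing a ganglion with nothing) agrees between truth and prediction.

## Validation scale

The standard validation study (also what `scripts/acceptance.py` runs) uses
twenty noise-free 1600×1600 fixtures at ρ = 1.5 px/μm with 5–15 ganglia and
2–7 extraganglionic neurons each (≈3,500 neurons in total), chosen as a
canvas comfortably holding the heavy-tailed size law at separation factor 2;
model-recovery checks use 50,000 simulated ganglion sizes per seed. On these
conditions the pipeline's neuron and ganglia counts match ground truth
exactly, detection precision and recall are 1.0, and co-clustering agreement
is 1.0.

## Degenerate inputs and edge behavior

A constant threshold region (e.g. an empty field) raises a degenerate-input
error rather than guessing a threshold; an empty foreground yields zero
peaks, zero ganglia and zero densities (mean size reported as missing);
zero-variance size lists refuse the NB fit; zero-variance manual counts
refuse the concordance fit. Peaks on image borders are allowed, since
stitched mosaics place tissue against the frame.

## Known limitations

* Strictly 2-D: Z-stacks are rejected, although real ganglia are 3-D.
* Single-channel analysis only; no multi-label colocalization.
* Watershed regions follow the binary mask's distance transform, so the
  per-pixel extent of a ganglion region is approximate; quantification is by
  neuron count, not region area.
* Densities default to the full image frame as "imaged area"; tissue that
  does not fill the frame requires an explicit area or mask for unbiased
  densities.
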