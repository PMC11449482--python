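# Methods

`somafret` quantifies γ-secretase activity cell by cell from two-channel
near-infrared confocal z-stacks of neurons expressing a C99-based FRET
biosensor (donor miRFP670, acceptor miRFP720), and asks whether a
neuron's acceptor/donor emission ratio (the "720/670 ratio") correlates
with the mean ratio of its spatial neighbors. This note records the
models, the defaults and why they were chosen, the numerical decisions,
and what the synthetic validation does and does not demonstrate.

## Pipeline model

The analysis is a fixed four-step image-processing chain followed by
measurement and spatial statistics:

1. **Background removal** — white top-hat (image minus grayscale
   opening) with a disk of radius 7 pixels, applied per 2-D slice to
   both channels identically. Per-slice (rather than 3-D) filtering is
   the default because uneven illumination varies laterally while the
   z-sampling (2 μm) is coarse relative to the 0.62 μm pixels; a 3-D
   ball-element mode is available via `filter_3d`. Border pixels use
   only the in-bounds part of the structuring element.
2. **Noise removal** — per-slice median filter, disk radius 3 pixels,
   both channels.
3. **Cell detection** — a threshold sweep builds a component forest:
   100 evenly spaced intensity levels spanning the nonzero range of the
   donor+acceptor sum channel; 26-connected components at each level,
   linked across adjacent levels by containment. Intensity-spaced (not
   quantile-spaced) levels are essential here: somata occupy ~1% of
   voxels, so mass-based levels would spend nearly the whole sweep
   inside the background noise floor and collapse the cells' dynamic
   range into one or two levels. Intensity spacing keeps the
   scale-invariance property (thresholds scale with the data, so
   segmentation is invariant to global gain) while resolving the
   objects. Candidate regions have 300–10000 voxels (inclusive); each
   candidate's stability is the relative volume change across ±1
   threshold level (ancestors give the lower side; the upper side
   follows single-child chains, with one-sided differences at chain
   ends and branch points, and 0 for components whose volume never
   changes). Within nested chains the most stable candidate wins; exact
   ties go to the smaller region (soma over soma+halo), then the lower
   level — fully deterministic. Segmenting the channel sum maximizes
   SNR without biasing the ratio.
4. **Morphological cleanup** — each ROI mask is opened in 3-D and ROIs
   whose opened volume drops below 300 voxels are removed (thin,
   irregular structures such as autofluorescent filaments). The
   structuring element is a *physically isotropic* sphere of radius
   2 × the lateral pixel size (1.24 μm at defaults): with 2 μm z-steps
   a plain 2-voxel ball would span 10 μm of tissue axially — more than
   a typical soma — and erase legitimate cells. For isotropic voxels
   the element reduces exactly to the standard radius-2 ball.

**Measurement.** Per ROI, the mean of each channel over the ROI's
voxels is taken on the preprocessed stack, and the FRET readout is the
ratio of means `mean_720 / mean_670` (not the mean of voxelwise
ratios) — this downweights dim edge voxels and is invariant under any
common rescaling of both channels. Centroids are unweighted voxel-center
means in physical μm. ROIs with ratio strictly below 1.5 are excluded as
autofluorescent: in these emission bands tissue autofluorescence has a
markedly lower acceptor/donor ratio than biosensor-expressing neurons.
Exclusion order is volume band → opening → ratio threshold, and every
excluded ROI carries an auditable reason (`volume | opening | ratio |
border`). Border-touching ROIs are retained but can be excluded with
`exclude_border`.

**Spatial statistics.** Distances are 3-D Euclidean in μm between ROI
centroids (a projected 2-D mode exists for sensitivity analysis).
Neighborhoods are either the k nearest other cells (k = 5 by default;
2 and 10 as standard alternates; ties broken by ascending label) or all
cells within an inclusive 20 μm radius. A cell is never its own
neighbor, and excluded cells are invisible to neighborhoods. The test
statistic is the Pearson correlation between each cell's ratio and its
neighbors' mean ratio, with a two-sided p from the t transform on n−2
degrees of freedom and significance at α = 0.001.

**Calibration of the p-value.** The t-based p assumes independent
pairs, but neighbor means overlap and reuse the same cell values, so
the parametric test is mildly anti-conservative for this statistic: on
simulated null scenes (250 cells, no spatial structure) we measure a
~1.6% rejection rate at nominal α = 0.001. The package therefore also
provides a seeded permutation test (ratios permuted across fixed
positions; neighbor means and r recomputed; two-sided empirical p
`(1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1)`) which is calibrated by
construction and is the recommended confirmatory inference. Null-control
validations use the permutation p; the parametric p is reported
alongside because it is the field's customary statistic.

## Synthetic-data generator

The generator emulates the acquisition the pipeline targets, with known
ground truth:

| parameter | default | rationale |
|---|---|---|
| field | 512×512 px at 0.62 μm/px, 60 planes at 2 μm (≈318×318×120 μm) | published pixel counts and z-step; the lateral pixel size is a plausible ×25/zoom-1 value and is configurable |
| cells per field | 250 | matches the reported ~200–250 ROIs per animal |
| placement | hard-core (dart throwing), min separation 12 μm, 8 μm margin | sparse AAV labeling keeps touching somata rare |
| soma radius | uniform 5.0–6.5 μm, Gaussian profile σ = r/2 cut at 2σ | cortical somata are ~10–15 μm across; the 2σ cut gives a crisp, blob-like boundary |
| brightness | log-normal, median 12 000 counts, σ_log 0.25, independent of ratio | bright overexpressed sensor imaged near the top of the detector range; high SNR so that per-voxel shot noise (~1%) does not bias the ratio through the top-hat noise floor; log-normal spread emulates uneven transduction |
| ratio field | mean 2.5, exponential covariance, sill 0.09, range 30 μm, nugget 0.01 | keeps ratios ~3σ above the 1.5 exclusion threshold; exponential is the simplest one-parameter range model for "neighboring cells are similar" |
| optics | PSF σ (1.2, 0.35, 0.35) μm, attenuation length 60 μm, background 20 + gradient 10, Poisson + Gaussian read noise (σ=2) | confocal-scale PSF; 60 μm decay makes ~120 μm-deep cells dim (≈13% amplitude) but segmentable, consistent with signal detectable to ~100 μm |
| distractors | 30 per field, ratio in [0.6, 1.2], brightness 0.3–0.9× median cell | three archetypes: sub-band small blobs, elongated thin filaments (destroyed by opening), soma-sized low-ratio blobs (caught only by the ratio filter) |

Acceptor signal is `true_ratio ×` the donor profile voxel by voxel, so
with optics and noise disabled rendering is exactly invertible: every
soma-interior voxel has acceptor/donor equal to the planted ratio, and
the full pipeline recovers planted ratios to ≤1e-6 relative error.
Placement, geometry, brightness, field, distractors and noise each draw
from independent hash-derived sub-streams of one master seed, so runs
are bit-reproducible and changing one stream leaves the others fixed.

Two switches emulate the pharmacological experiment: a global
multiplicative scaling of all cell ratios (inhibitor effect on the mean;
distractors untouched) and a random permutation of ratios across
positions (destroys spatial structure while preserving the ratio
distribution — the no-correlation null).

**What the simulation does not capture.** Somata are quasi-spherical
with a single brightness scale — no dendrites/axons, no partial-volume
neighbors touching, no vasculature shadows or scattering, no chromatic
offset between channels, no motion. The background is a smooth plane
plus white noise, not structured tissue autofluorescence. Passing these
validations therefore demonstrates the *pipeline's* correctness on data
satisfying its stated model, not robustness to every in-vivo artifact.

## Numerical and design choices

- The top-hat leaves a positive noise-floor offset (~1σ of the local
  shot noise) in both channels; being common-mode it compresses ratios
  toward 1 by roughly `ε(r−1)/s̄` for mean ROI signal `s̄`. At the
  default brightness this bias is ~1% on average (up to ~5% for the
  deepest, dimmest cells); at few-hundred-count signals it would reach
  ~10–20%, which is why the generator's default is a high-SNR regime.
- Degenerate inputs: constant volumes produce an empty component
  forest; zero-variance correlations are reported explicitly as
  degenerate (never silent NaN); an ROI with zero mean donor intensity
  is excluded with a logged warning; duplicate cell positions with a
  zero nugget raise on the non-positive-definite covariance.
- Thresholds at exactly the volume-band edges are included (inclusive
  band); a ratio exactly at 1.5 is retained (strictly-below exclusion);
  the 20 μm radius is inclusive.
- TIFFs are written as OME with physical voxel sizes; both OME and
  ImageJ metadata are read (OME preferred); an explicit override wins
  with a logged notice. Large stacks are persisted as float32; all
  statistics are computed in float64.
- Validation problem sizes: the full-scale checks run one to five
  replicates of the default 512×512×60 scene; replicate-heavy checks
  (null control, contrast recovery, pipeline spot-checks) use a
  density-matched 300×300 px field with 86 cells, and distribution-level
  checks (type-I, power) use the ground-truth oracle path at 250 cells
  over 50–200 seeds. These sizes were chosen to exercise the same
  statistical regime as the full field while keeping the suite quick to
  run.

## Known limitations

- No watershed splitting: somata closer than ~the sum of their radii
  can merge into one component and both cells are then lost to the
  volume band or matched as one; the hard-core placement keeps this
  rare (~1–3% of cells at defaults).
- The MSER reconstruction (level spacing, δ=1 stability, tie rules) is
  a principled reimplementation of the cited plugin's behavior, not a
  bit-exact port; its parameters are configurable.
- The parametric neighbor-correlation p is anti-conservative (above);
  conclusions at the α = 0.001 level should rest on the permutation p.
- Depth-dependent bias: the deepest cells carry a small systematic
  downward ratio error (noise-floor compression); analyses contrasting
  depths should model or restrict depth.
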