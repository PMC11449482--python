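# somafret

Cell-by-cell ratiometric FRET analysis of two-channel 3-D confocal
stacks, built for in-vivo recordings of γ-secretase activity with
near-infrared biosensors.

Neurons expressing a C99-based FRET substrate emit in two bands — donor
miRFP670 and acceptor miRFP720 — and the per-cell acceptor/donor
emission ratio (the **720/670 ratio**) reports endogenous γ-secretase
activity. `somafret` turns a raw two-channel z-stack into per-neuron
ratios and asks a spatial question: *does a neuron's γ-secretase
activity correlate with the activity of its neighbors?*

The pipeline (for each stack):

1. **Preprocess** — per-slice white top-hat (disk r=7) removes uneven
   background; per-slice median filter (disk r=3) removes noise.
   Identical filtering of both channels keeps ratios unbiased.
2. **Segment** — 3-D iterative thresholding over the donor+acceptor
   sum with an MSER (maximally-stable-extremal-regions) criterion
   draws ROIs on cell bodies of 300–10000 voxels, followed by a 3-D
   morphological opening (r=2) that removes thin misassigned objects.
3. **Measure** — per ROI, mean donor and acceptor intensity and the
   ratio of means r = mean₇₂₀ / mean₆₇₀; ROIs with r < 1.5 are
   excluded as autofluorescent objects.
4. **Spatial statistics** — for each retained cell, the mean ratio of
   its k nearest neighbors (k ∈ {2, 5, 10}) or of all cells within a
   20 μm radius; Pearson correlation between rᵢ and the neighbor mean
   r̄ᵢ, with a parametric two-sided p (t transform, n−2 df, α = 0.001)
   and a seeded permutation test as the calibrated confirmatory
   inference.

A first-class synthetic-data module renders ground-truth scenes —
hard-core-placed somata, a latent ratio field with exponential spatial
covariance C(d) = σ²·exp(−d/ρ) + nugget, autofluorescent distractors,
Gaussian PSF, depth attenuation, Poisson and read noise — so every
stage is validated against known truth. See `docs/methods.md` for the
models, defaults and their rationale.

## Worked example

Simulate a field with spatially clustered ratios, run the full
pipeline, and read the neighbor correlation:

```python
import somafret as sf
from somafret.config import subseed

seed = 1
scene = sf.make_scene(seed=seed)                       # ~250 somata, 318x318x120 um
scene = sf.add_distractors(scene, 30, seed=subseed(seed, "distractors"))
result = sf.run_pipeline(sf.PipelineConfig(seed=seed), scene=scene,
                         out_dir="runs/demo", n_perm=1999)
print(result.report["n_retained"], result.correlations["knn_5"])
```

prints (numbers from this exact seed):

```
244 {'r': 0.5840541185864843, 'p_value': 1.0360618812695093e-23, 'n': 244,
     'alpha': 0.001, 'significant': True, 'degenerate': False,
     'spec': 'knn(k=5)', 'permutation_p': 0.0005}
```

244 of the 250 planted cells were retained (the 30 low-ratio
distractors were all excluded, with reasons logged per ROI in
`records.csv`), and each cell's 720/670 ratio correlates with the mean
ratio of its five nearest neighbors at r ≈ 0.58 — recovering the
spatial clustering planted by the 30 μm-range ratio field. Shuffling
the ratios across positions (`sf.shuffle_ratio_positions`) destroys the
correlation, and `sf.compare_conditions` on a pair of runs differing by
a global ratio scaling recovers the planted percentage change —
emulating an inhibitor experiment.

The same stages are available from a shell:

```bash
somafret run runs/demo --simulate --seed 1        # full pipeline
somafret simulate stack.tif truth.json --seed 1   # stack + ground truth
somafret preprocess stack.tif pre.tif
somafret segment pre.tif labels.tif
somafret measure pre.tif labels.tif records.csv
somafret spatial records.csv report.json
somafret compare runs/pre runs/post
```

Each run directory contains the resolved config, the preprocessed
stack, the ROI label volume, the per-cell table, correlation reports
for all four neighborhood definitions, a pseudo-color ratio rendering,
and a log with object counts at every filter stage.

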