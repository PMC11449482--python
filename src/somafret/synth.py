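"""Synthetic two-channel 3-D stacks with known per-cell ground truth.

The generator emulates in-vivo NIR confocal fields of AAV-labeled
cortical neurons expressing a donor/acceptor FRET biosensor:

* ~250 quasi-spherical somata placed by a hard-core process (minimum
  pairwise separation) in a ~318x318x120 μm field;
* a latent per-cell 720/670 ratio drawn from a Gaussian random field
  with exponential covariance ``C(d) = sill*exp(-d/range_um)`` plus a
  nugget, so spatial clustering of the ratio is tunable from none
  (nugget only) to strong;
* low-ratio autofluorescent distractors whose size or morphology
  violates the segmentation filters, or whose ratio falls below the 1.5
  exclusion threshold;
* an optical model: Gaussian soma profiles (cut at 2σ), Gaussian PSF,
  exponential depth attenuation, uneven background (offset + smooth
  gradient), Poisson shot noise and additive Gaussian read noise.

Every stage of the analysis pipeline can therefore be validated against
exact ground truth.  Placement, field, and noise randomness are
independent sub-streams of one master seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .config import subseed
from .io import ImageStack
from .spatial import CorrelationResult, NeighborhoodSpec, correlate_with_neighbors

__all__ = [
    "CellTruth",
    "DistractorTruth",
    "RatioFieldParams",
    "OpticsParams",
    "SyntheticScene",
    "sample_cell_centers",
    "sample_ratio_field",
    "make_scene",
    "add_distractors",
    "render_stack",
    "apply_global_ratio_scaling",
    "shuffle_ratio_positions",
    "oracle_neighbor_correlation",
    "write_scene",
    "read_scene",
]


@dataclass
class CellTruth:
    """Ground truth for one soma: position, size, brightness, ratio."""

    center_um: tuple[float, float, float]  # (z, y, x)
    radius_um: float
    donor_amplitude: float
    true_ratio: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.donor_amplitude <= 0 or self.true_ratio <= 0:
            raise ValueError("radius, amplitude and ratio must all be > 0")


@dataclass
class DistractorTruth:
    """A planted non-neuronal autofluorescent object.

    Its ratio is drawn below the 1.5 exclusion threshold; its size or
    shape additionally violates the volume band or the opening filter
    for the small / elongated archetypes.
    """

    center_um: tuple[float, float, float]
    shape: Literal["small-blob", "irregular-elongated"]
    volume_voxels: int
    amplitude: float
    true_ratio: float
    radius_um: float = 2.0
    waypoints_um: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.true_ratio < 1.5:
            raise ValueError("distractor ratios must be < 1.5")


@dataclass
class RatioFieldParams:
    """Spatial covariance of the latent per-cell ratio field.

    ``C(d) = sill * exp(-d / range_um) + nugget * 1[d = 0]`` around
    ``mean_ratio``.  Defaults give a mean ratio of 2.5 with sd ~0.32 and
    a 30 μm correlation length, keeping essentially all cell ratios
    above the 1.5 autofluorescence threshold.
    """

    mean_ratio: float = 2.5
    sill: float = 0.09
    range_um: float = 30.0
    nugget: float = 0.01

    def __post_init__(self) -> None:
        if self.sill < 0 or self.nugget < 0:
            raise ValueError("sill and nugget must be >= 0")
        if self.range_um <= 0:
            raise ValueError("range_um must be > 0")
        if self.mean_ratio - 3.0 * math.sqrt(self.sill + self.nugget) <= 0:
            raise ValueError("mean_ratio - 3*sd must stay positive")


@dataclass
class OpticsParams:
    """Acquisition model: PSF, background, depth attenuation, noise."""

    psf_sigma_um: tuple[float, float, float] = (1.2, 0.35, 0.35)  # (z, y, x)
    background_offset: float = 20.0
    background_gradient_amplitude: float = 10.0
    attenuation_length_um: float = 60.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.psf_sigma_um):
            raise ValueError("psf_sigma_um must be >= 0 componentwise")
        if self.attenuation_length_um <= 0:
            raise ValueError("attenuation_length_um must be > 0")

    @classmethod
    def noise_free(cls) -> "OpticsParams":
        """No PSF, no background, no noise — rendering is exactly invertible."""
        return cls(
            psf_sigma_um=(0.0, 0.0, 0.0),
            background_offset=0.0,
            background_gradient_amplitude=0.0,
            read_noise_sd=0.0,
            shot_noise=False,
        )


@dataclass
class SyntheticScene:
    """Ground truth of one simulated field."""

    field_dims_um: tuple[float, float, float]  # (z, y, x) extent
    voxel_size_um: tuple[float, float, float]  # (dz, dy, dx)
    cells: list[CellTruth]
    distractors: list[DistractorTruth]
    field_params: RatioFieldParams
    rng_seed: int

    def cell_centers(self) -> np.ndarray:
        return np.array([c.center_um for c in self.cells]).reshape(-1, 3)

    def cell_ratios(self) -> np.ndarray:
        return np.array([c.true_ratio for c in self.cells])

    def stack_shape(self) -> tuple[int, int, int]:
        shape = []
        for ext, vs in zip(self.field_dims_um, self.voxel_size_um):
            n = ext / vs
            if abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise ValueError(
                    f"field extent {ext} um is not a positive integer multiple of "
                    f"voxel size {vs} um"
                )
            shape.append(int(round(n)))
        return tuple(shape)


# ---------------------------------------------------------------------------
# Ground-truth sampling


def sample_cell_centers(
    n: int,
    field_dims_um: Sequence[float],
    min_separation_um: float,
    seed: int,
    margin_um: float = 8.0,
    max_attempts_per_point: int = 2000,
) -> list[tuple[float, float, float]]:
    """Hard-core placement of cell centers by dart throwing.

    Centers are uniform in the field shrunk by ``margin_um`` on every
    face (so somata stay inside the imaged volume), rejecting any draw
    closer than ``min_separation_um`` to an accepted point.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if min_separation_um < 0:
        raise ValueError("min_separation_um must be >= 0")
    dims = np.asarray(field_dims_um, dtype=float)
    lo = np.minimum(margin_um, dims / 2)
    hi = dims - lo
    if np.any(hi <= lo):
        raise ValueError("field too small for the requested margin")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    pts = np.empty((0, 3))
    for i in range(n):
        for _ in range(max_attempts_per_point):
            p = rng.uniform(lo, hi)
            if pts.size == 0 or np.min(np.linalg.norm(pts - p, axis=1)) >= min_separation_um:
                accepted.append(p)
                pts = np.vstack([pts, p[None]]) if pts.size else p[None].copy()
                break
        else:
            raise RuntimeError(
                f"could not place point {i + 1}/{n} after {max_attempts_per_point} "
                f"attempts; field {tuple(dims)} um cannot hold {n} points with "
                f"min separation {min_separation_um} um"
            )
    return [tuple(float(v) for v in p) for p in accepted]


def sample_ratio_field(
    centers: Sequence[Sequence[float]], params: RatioFieldParams, seed: int
) -> list[float]:
    """Draw per-cell true ratios from the spatial Gaussian random field.

    Multivariate normal with mean ``mean_ratio`` and covariance
    ``sill * exp(-d / range_um) + nugget`` on the diagonal.  A
    non-positive-definite covariance (e.g. duplicate centers with zero
    nugget) is an explicit failure.
    """
    pts = np.asarray(centers, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ValueError("centers must be nonempty")
    d = cdist(pts, pts)
    cov = params.sill * np.exp(-d / params.range_um)
    cov[np.diag_indices_from(cov)] += params.nugget
    if params.sill == 0 and params.nugget == 0:
        return [float(params.mean_ratio)] * pts.shape[0]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "ratio-field covariance is not positive definite "
            "(duplicate centers with nugget=0?)"
        ) from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(pts.shape[0])
    ratios = params.mean_ratio + chol @ z
    return [float(r) for r in ratios]


def make_scene(
    seed: int,
    n_cells: int = 250,
    field_dims_um: tuple[float, float, float] = (120.0, 317.44, 317.44),
    voxel_size_um: tuple[float, float, float] = (2.0, 0.62, 0.62),
    min_separation_um: float = 12.0,
    field_params: RatioFieldParams | None = None,
    radius_range_um: tuple[float, float] = (5.0, 6.5),
    amplitude_log_mean: float = math.log(12000.0),
    amplitude_log_sd: float = 0.25,
) -> SyntheticScene:
    """Generate a default ground-truth scene from one master seed.

    Defaults emulate the published acquisition: a 512x512 px field at
    0.62 μm/px, 60 z-planes at 2 μm steps, ~250 labeled somata of
    5–6.5 μm radius, log-normal brightness (uneven AAV transduction),
    and a spatially structured ratio field (mean 2.5, 30 μm range).
    Placement, sizes, brightness and the ratio field each consume an
    independent sub-stream of the master seed; brightness is sampled
    independently of the ratio field, so expression level carries no
    information about the ratio.
    """
    field_params = field_params or RatioFieldParams()
    centers = sample_cell_centers(
        n_cells, field_dims_um, min_separation_um, seed=subseed(seed, "placement")
    )
    if n_cells > 0:
        ratios = sample_ratio_field(centers, field_params, seed=subseed(seed, "field"))
    else:
        ratios = []
    rng_geom = np.random.default_rng(subseed(seed, "geometry"))
    radii = rng_geom.uniform(*radius_range_um, size=n_cells)
    rng_amp = np.random.default_rng(subseed(seed, "amplitude"))
    amps = np.exp(rng_amp.normal(amplitude_log_mean, amplitude_log_sd, size=n_cells))
    cells = [
        CellTruth(center_um=c, radius_um=float(r), donor_amplitude=float(a), true_ratio=float(t))
        for c, r, a, t in zip(centers, radii, amps, ratios)
    ]
    return SyntheticScene(
        field_dims_um=tuple(float(v) for v in field_dims_um),
        voxel_size_um=tuple(float(v) for v in voxel_size_um),
        cells=cells,
        distractors=[],
        field_params=field_params,
        rng_seed=seed,
    )


def add_distractors(
    scene: SyntheticScene,
    n_distractors: int,
    ratio_low: float = 0.6,
    ratio_high: float = 1.2,
    seed: int = 0,
) -> SyntheticScene:
    """Plant low-ratio autofluorescent objects in a copy of the scene.

    Three archetypes are cycled: sub-band small blobs (too few voxels),
    irregular elongated filaments (in the volume band but destroyed by
    the morphological opening), and soma-sized blobs whose only
    violation is their low 720/670 ratio.  All distractor ratios fall in
    ``[ratio_low, ratio_high]`` and must stay below the 1.5 exclusion
    threshold.
    """
    if not 0 < ratio_low <= ratio_high < 1.5:
        raise ValueError("require 0 < ratio_low <= ratio_high < 1.5")
    out = dataclasses.replace(
        scene, cells=list(scene.cells), distractors=list(scene.distractors)
    )
    if n_distractors == 0:
        return out
    rng = np.random.default_rng(seed)
    dims = np.asarray(scene.field_dims_um)
    voxel_volume = float(np.prod(scene.voxel_size_um))
    existing = (
        scene.cell_centers() if scene.cells else np.empty((0, 3))
    )
    for i in range(n_distractors):
        archetype = ("small-blob", "irregular-elongated", "ratio-only-blob")[i % 3]
        for _ in range(2000):
            center = rng.uniform(8.0, dims - 8.0)
            if existing.size == 0 or np.min(
                np.linalg.norm(existing - center, axis=1)
            ) >= 10.0:
                break
        else:
            raise RuntimeError("could not place distractor away from cells")
        existing = np.vstack([existing, center[None]])
        ratio = float(rng.uniform(ratio_low, ratio_high))
        # bright enough to be segmented alongside the cells, as real
        # autofluorescent granules are — otherwise the filters are idle
        ref_amp = (
            float(np.median([c.donor_amplitude for c in scene.cells]))
            if scene.cells
            else 12000.0
        )
        amplitude = float(rng.uniform(0.3, 0.9) * ref_amp)
        if archetype == "small-blob":
            radius = float(rng.uniform(1.5, 2.5))
            vol = int(4.0 / 3.0 * math.pi * radius**3 / voxel_volume)
            d = DistractorTruth(
                center_um=tuple(center),
                shape="small-blob",
                volume_voxels=vol,
                amplitude=amplitude,
                true_ratio=ratio,
                radius_um=radius,
            )
        elif archetype == "ratio-only-blob":
            radius = float(rng.uniform(4.0, 5.0))
            vol = int(4.0 / 3.0 * math.pi * radius**3 / voxel_volume)
            d = DistractorTruth(
                center_um=tuple(center),
                shape="small-blob",
                volume_voxels=vol,
                amplitude=amplitude,
                true_ratio=ratio,
                radius_um=radius,
            )
        else:
            # thin tube along a jittered 3-D polyline: in the volume band
            # but thinner than the opening ball, so it never survives
            n_seg = 12
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            step = 6.0
            waypoints = [center.copy()]
            for _ in range(n_seg):
                direction = direction + 0.4 * rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                nxt = np.clip(waypoints[-1] + step * direction, 4.0, dims - 4.0)
                waypoints.append(nxt)
            tube_radius = 1.0
            length = step * n_seg
            vol = int(math.pi * tube_radius**2 * length / voxel_volume)
            d = DistractorTruth(
                center_um=tuple(center),
                shape="irregular-elongated",
                volume_voxels=vol,
                amplitude=amplitude,
                true_ratio=ratio,
                radius_um=tube_radius,
                waypoints_um=[tuple(float(v) for v in w) for w in waypoints],
            )
        out.distractors.append(d)
    return out


# ---------------------------------------------------------------------------
# Scene transforms (condition emulation)


def apply_global_ratio_scaling(scene: SyntheticScene, factor: float) -> SyntheticScene:
    """Scale every cell's true ratio by ``factor`` (distractors untouched).

    Emulates a pharmacological shift of the FRET readout, e.g. protease
    inhibition lowering the acceptor/donor ratio uniformly.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    cells = [dataclasses.replace(c, true_ratio=c.true_ratio * factor) for c in scene.cells]
    return dataclasses.replace(scene, cells=cells, distractors=list(scene.distractors))


def shuffle_ratio_positions(scene: SyntheticScene, seed: int) -> SyntheticScene:
    """Permute the cells' true ratios across positions.

    The multiset of ratios is preserved while any spatial structure is
    destroyed — the null condition in which no neighbor correlation
    should be detected.
    """
    if len(scene.cells) < 2:
        raise ValueError("shuffling needs at least 2 cells")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(scene.cells))
    ratios = [scene.cells[j].true_ratio for j in perm]
    cells = [
        dataclasses.replace(c, true_ratio=r) for c, r in zip(scene.cells, ratios)
    ]
    return dataclasses.replace(scene, cells=cells, distractors=list(scene.distractors))


def oracle_neighbor_correlation(
    scene: SyntheticScene,
    neighborhood_spec: NeighborhoodSpec | None = None,
    alpha: float = 0.001,
) -> CorrelationResult:
    """Neighbor-mean correlation computed on ground truth.

    Uses the true centers and true ratios, bypassing rendering and
    segmentation, but the identical neighborhood/correlation code path
    as the imaging pipeline — the oracle against which pipeline results
    are compared.
    """
    if len(scene.cells) < 3:
        raise ValueError("oracle correlation needs at least 3 cells")
    spec = neighborhood_spec or NeighborhoodSpec()
    labels = list(range(1, len(scene.cells) + 1))
    result, _ = correlate_with_neighbors(
        labels, scene.cell_centers(), scene.cell_ratios(), spec, alpha=alpha
    )
    return result


# ---------------------------------------------------------------------------
# Rendering


def _paint_blob(
    density: np.ndarray,
    center_um: Sequence[float],
    radius_um: float,
    amplitude: float,
    voxel_size_um: Sequence[float],
) -> None:
    """Add a Gaussian-profile sphere (σ = radius/2, cut at 2σ) in place."""
    vs = np.asarray(voxel_size_um, dtype=float)
    center = np.asarray(center_um, dtype=float)
    sigma = radius_um / 2.0
    lo_vox = np.maximum(np.floor((center - radius_um) / vs).astype(int), 0)
    hi_vox = np.minimum(np.ceil((center + radius_um) / vs).astype(int) + 1, density.shape)
    if np.any(hi_vox <= lo_vox):
        return
    grids = np.meshgrid(
        *[(np.arange(lo, hi) + 0.5) * v - c for lo, hi, v, c in zip(lo_vox, hi_vox, vs, center)],
        indexing="ij",
    )
    d2 = sum(g * g for g in grids)
    profile = amplitude * np.exp(-d2 / (2.0 * sigma**2))
    profile[d2 > radius_um**2] = 0.0
    sl = tuple(slice(lo, hi) for lo, hi in zip(lo_vox, hi_vox))
    density[sl] += profile


def _paint_tube(
    density: np.ndarray,
    waypoints_um: Sequence[Sequence[float]],
    tube_radius_um: float,
    amplitude: float,
    voxel_size_um: Sequence[float],
) -> None:
    """Add a thin uniform tube along a polyline, in place."""
    vs = np.asarray(voxel_size_um, dtype=float)
    pts = np.asarray(waypoints_um, dtype=float)
    # dense sample along the polyline, then a uniform stamp per sample
    for a, b in zip(pts[:-1], pts[1:]):
        seg_len = float(np.linalg.norm(b - a))
        n_samp = max(int(seg_len / min(vs) * 2), 2)
        for t in np.linspace(0.0, 1.0, n_samp, endpoint=False):
            p = a + t * (b - a)
            lo_vox = np.maximum(np.floor((p - tube_radius_um) / vs).astype(int), 0)
            hi_vox = np.minimum(
                np.ceil((p + tube_radius_um) / vs).astype(int) + 1, density.shape
            )
            if np.any(hi_vox <= lo_vox):
                continue
            grids = np.meshgrid(
                *[
                    (np.arange(lo, hi) + 0.5) * v - c
                    for lo, hi, v, c in zip(lo_vox, hi_vox, vs, p)
                ],
                indexing="ij",
            )
            d2 = sum(g * g for g in grids)
            sl = tuple(slice(lo, hi) for lo, hi in zip(lo_vox, hi_vox))
            region = density[sl]
            np.maximum(region, np.where(d2 <= tube_radius_um**2, amplitude, 0.0), out=region)


def render_stack(scene: SyntheticScene, optics: OpticsParams, seed: int = 0) -> ImageStack:
    """Render a scene into a two-channel stack under the optics model.

    For each object the donor channel receives ``amplitude x profile``
    and the acceptor channel ``true_ratio x`` the same profile, so the
    per-voxel acceptor/donor ratio inside an isolated object equals its
    true ratio exactly.  Signal is PSF-convolved and attenuated as
    ``exp(-z / attenuation_length_um)``; background (offset plus a
    smooth tilted-plane gradient) is added; Poisson shot noise is
    applied to the noise-free photon image, then additive Gaussian read
    noise.  The scene's ground truth is never modified.
    """
    shape = scene.stack_shape()
    vs = np.asarray(scene.voxel_size_um)
    donor = np.zeros(shape, dtype=np.float64)
    acceptor = np.zeros(shape, dtype=np.float64)
    for c in scene.cells:
        _paint_blob(donor, c.center_um, c.radius_um, c.donor_amplitude, vs)
        _paint_blob(acceptor, c.center_um, c.radius_um, c.donor_amplitude * c.true_ratio, vs)
    for d in scene.distractors:
        if d.shape == "irregular-elongated" and d.waypoints_um:
            _paint_tube(donor, d.waypoints_um, d.radius_um, d.amplitude, vs)
            _paint_tube(acceptor, d.waypoints_um, d.radius_um, d.amplitude * d.true_ratio, vs)
        else:
            _paint_blob(donor, d.center_um, d.radius_um, d.amplitude, vs)
            _paint_blob(acceptor, d.center_um, d.radius_um, d.amplitude * d.true_ratio, vs)

    if any(s > 0 for s in optics.psf_sigma_um):
        sigma_vox = np.asarray(optics.psf_sigma_um) / vs
        donor = ndimage.gaussian_filter(donor, sigma=sigma_vox)
        acceptor = ndimage.gaussian_filter(acceptor, sigma=sigma_vox)

    z_um = (np.arange(shape[0]) + 0.5) * vs[0]
    atten = np.exp(-z_um / optics.attenuation_length_um)[:, None, None]
    donor *= atten
    acceptor *= atten

    rng = np.random.default_rng(seed)
    if optics.background_offset or optics.background_gradient_amplitude:
        yy = (np.arange(shape[1]) + 0.5) / shape[1]
        xx = (np.arange(shape[2]) + 0.5) / shape[2]
        theta = rng.uniform(0.0, 2.0 * math.pi)
        ramp = math.cos(theta) * yy[:, None] + math.sin(theta) * xx[None, :]
        ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1e-12)
        bg = optics.background_offset + optics.background_gradient_amplitude * ramp
        donor = donor + bg[None, :, :]
        acceptor = acceptor + bg[None, :, :]

    if optics.shot_noise:
        donor = rng.poisson(donor).astype(np.float64)
        acceptor = rng.poisson(acceptor).astype(np.float64)
    if optics.read_noise_sd > 0:
        donor = donor + rng.normal(0.0, optics.read_noise_sd, size=shape)
        acceptor = acceptor + rng.normal(0.0, optics.read_noise_sd, size=shape)
    np.maximum(donor, 0.0, out=donor)
    np.maximum(acceptor, 0.0, out=acceptor)
    return ImageStack(
        data=np.stack([donor, acceptor]), voxel_size_um=tuple(float(v) for v in vs)
    )


# ---------------------------------------------------------------------------
# Ground-truth serialization


def write_scene(scene: SyntheticScene, path: str | Path) -> Path:
    """Serialize a scene's ground truth to JSON."""
    path = Path(path)
    payload = {
        "field_dims_um": list(scene.field_dims_um),
        "voxel_size_um": list(scene.voxel_size_um),
        "rng_seed": scene.rng_seed,
        "field_params": dataclasses.asdict(scene.field_params),
        "cells": [dataclasses.asdict(c) for c in scene.cells],
        "distractors": [dataclasses.asdict(d) for d in scene.distractors],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_scene(path: str | Path) -> SyntheticScene:
    payload = json.loads(Path(path).read_text())
    cells = [
        CellTruth(
            center_um=tuple(c["center_um"]),
            radius_um=c["radius_um"],
            donor_amplitude=c["donor_amplitude"],
            true_ratio=c["true_ratio"],
        )
        for c in payload["cells"]
    ]
    distractors = [
        DistractorTruth(
            center_um=tuple(d["center_um"]),
            shape=d["shape"],
            volume_voxels=d["volume_voxels"],
            amplitude=d["amplitude"],
            true_ratio=d["true_ratio"],
            radius_um=d.get("radius_um", 2.0),
            waypoints_um=[tuple(w) for w in d.get("waypoints_um", [])],
        )
        for d in payload["distractors"]
    ]
    return SyntheticScene(
        field_dims_um=tuple(payload["field_dims_um"]),
        voxel_size_um=tuple(payload["voxel_size_um"]),
        cells=cells,
        distractors=distractors,
        field_params=RatioFieldParams(**payload["field_params"]),
        rng_seed=payload["rng_seed"],
    )
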