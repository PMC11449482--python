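"""Pipeline configuration.

All tunable parameters of the analysis live in one dataclass so that a run
is fully described by a single config file plus a master seed.  Defaults
follow the published protocol for in-vivo NIR FRET imaging of cortical
neurons: top-hat radius 7, median radius 3, ROI volume band 300–10000
voxels, morphological opening radius 2, autofluorescence ratio threshold
1.5, five nearest neighbors / 20 μm radius neighborhoods, and a 0.001
significance level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = ["PipelineConfig", "load_config", "subseed"]


@dataclass
class PipelineConfig:
    """Parameters of the segmentation / measurement / spatial pipeline.

    Attributes
    ----------
    tophat_radius_vox
        Disk radius (voxels) of the white top-hat used for background
        removal, applied per 2-D slice.
    median_radius_vox
        Disk radius (voxels) of the per-slice median filter.
    threshold_levels
        Number of evenly spaced intensity quantiles swept when building the
        component tree.
    volume_min_vox, volume_max_vox
        Inclusive ROI volume band in voxels; candidate regions outside the
        band are never selected.
    opening_radius_vox
        Ball radius (voxels) of the 3-D morphological opening applied to
        each ROI mask after selection.
    ratio_threshold
        ROIs with acceptor/donor (720/670) ratio strictly below this value
        are excluded as autofluorescent objects.
    neighbor_k
        Number of nearest neighbors in kNN mode.
    neighbor_radius_um
        Neighborhood radius (μm) in radius mode (inclusive).
    alpha
        Two-sided significance level for correlation tests.
    filter_3d
        If True, top-hat and median filtering use 3-D ball structuring
        elements instead of per-slice disks.
    exclude_border
        If True, ROIs touching the stack border are excluded (flagged
        ``border``); by default they are retained but flagged in logs.
    distances_2d
        If True, neighbor distances ignore the z coordinate (projected
        mode); default is full 3-D Euclidean distance in μm.
    seed
        Master seed; per-stage seeds are derived from it with
        :func:`subseed`.
    """

    tophat_radius_vox: int = 7
    median_radius_vox: int = 3
    threshold_levels: int = 100
    delta_levels: int = 1
    volume_min_vox: int = 300
    volume_max_vox: int = 10000
    opening_radius_vox: int = 2
    ratio_threshold: float = 1.5
    neighbor_k: int = 5
    neighbor_radius_um: float = 20.0
    alpha: float = 0.001
    filter_3d: bool = False
    exclude_border: bool = False
    distances_2d: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tophat_radius_vox < 1 or self.median_radius_vox < 1:
            raise ValueError("filter radii must be >= 1")
        if self.threshold_levels < 3:
            raise ValueError("threshold_levels must be >= 3")
        if self.volume_min_vox > self.volume_max_vox:
            raise ValueError("volume_min_vox must be <= volume_max_vox")
        if self.opening_radius_vox < 1:
            raise ValueError("opening_radius_vox must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.neighbor_k < 1:
            raise ValueError("neighbor_k must be >= 1")
        if self.neighbor_radius_um <= 0:
            raise ValueError("neighbor_radius_um must be > 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path, **overrides: Any) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML or JSON file.

    Keyword overrides win over file values; unknown keys are an error so
    typos cannot silently fall back to defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update(overrides)
    return PipelineConfig(**data)


def subseed(master_seed: int, stream: str) -> int:
    """Derive a deterministic per-stage seed from a master seed.

    Independent named streams (``placement``, ``field``, ``noise`` ...)
    keep the simulator's randomness decoupled: changing the noise stream
    never moves the cells.
    """
    h = hashlib.sha256(f"{master_seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def seeded_rng(master_seed: int, stream: str) -> np.random.Generator:
    """A NumPy generator for one named sub-stream of a master seed."""
    return np.random.default_rng(subseed(master_seed, stream))
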