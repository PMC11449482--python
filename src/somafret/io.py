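"""On-disk artifacts: multi-channel TIFF stacks, label volumes, tables.

The two-channel stacks hold donor (miRFP670) emission in channel 0 and
acceptor (miRFP720) emission in channel 1, ordered (channel, z, y, x).
Stacks are written as OME-TIFF with physical voxel sizes; both OME and
ImageJ metadata are understood at read time (OME preferred).  Per-cell
results go to CSV with a fixed, documented column order, and retained
ROIs can be rendered to a pseudo-color ratio projection.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile
from matplotlib import colormaps
from matplotlib.colors import Normalize

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "CellRecord",
    "RECORD_COLUMNS",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "write_records_table",
    "read_records_table",
    "render_pseudocolor",
]

#: Channel order of every ImageStack: donor emission first.
CHANNEL_NAMES = ("donor_670", "acceptor_720")

#: Fixed column order of the per-cell results table.
RECORD_COLUMNS = [
    "label",
    "volume_vox",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "mean_670",
    "mean_720",
    "ratio_720_670",
    "excluded_reason",
]

EXCLUSION_REASONS = ("none", "volume", "opening", "ratio", "border")


@dataclass
class ImageStack:
    """A two-channel 3-D intensity volume with physical voxel sizes.

    ``data`` is (2, z, y, x) with channel 0 = donor (670 nm emission) and
    channel 1 = acceptor (720 nm emission).  ``voxel_size_um`` is
    (dz, dy, dx) in μm.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != 2:
            raise ValueError(
                f"stack data must be (2, z, y, x), got shape {self.data.shape}"
            )
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size_um must be 3 positive values (dz, dy, dx)")
        self.voxel_size_um = vs

    @property
    def donor(self) -> np.ndarray:
        return self.data[0]

    @property
    def acceptor(self) -> np.ndarray:
        return self.data[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def sum_channel(self) -> np.ndarray:
        """Donor + acceptor, the default segmentation input."""
        return self.data[0].astype(np.float64) + self.data[1].astype(np.float64)


@dataclass
class CellRecord:
    """One segmented object and its FRET measurement."""

    label: int
    volume_vox: int
    centroid_um: tuple[float, float, float]  # (z, y, x)
    mean_670: float
    mean_720: float
    ratio_720_670: float
    excluded_reason: str = "none"

    def __post_init__(self) -> None:
        if self.excluded_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown excluded_reason {self.excluded_reason!r}")

    @property
    def retained(self) -> bool:
        return self.excluded_reason == "none"


# ---------------------------------------------------------------------------
# TIFF stacks


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with voxel sizes in the OME metadata."""
    path = Path(path)
    dz, dy, dx = stack.voxel_size_um
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(CHANNEL_NAMES)},
        },
    )
    return path


def _voxel_size_from_metadata(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (dz, dy, dx) in μm from OME or ImageJ metadata (OME wins)."""
    if tif.ome_metadata:
        m = tif.ome_metadata
        sizes = {}
        for ax in "XYZ":
            match = re.search(rf'PhysicalSize{ax}="([\d.eE+-]+)"', m)
            if match:
                sizes[ax] = float(match.group(1))
        if {"X", "Y", "Z"} <= sizes.keys():
            return (sizes["Z"], sizes["Y"], sizes["X"])
    if tif.imagej_metadata:
        ij = tif.imagej_metadata
        dz = ij.get("spacing")
        page = tif.pages[0]
        try:
            xres = page.tags["XResolution"].value
            yres = page.tags["YResolution"].value
            dx = xres[1] / xres[0]
            dy = yres[1] / yres[0]
        except (KeyError, ZeroDivisionError):
            dx = dy = None
        if dz is not None and dx and dy:
            return (float(dz), float(dy), float(dx))
    return None


def read_stack(
    path: str | Path,
    voxel_size_override: tuple[float, float, float] | None = None,
    *,
    swap_channels: bool = False,
) -> ImageStack:
    """Read a two-channel z-stack TIFF.

    Voxel sizes come from OME metadata, falling back to ImageJ metadata;
    an explicit ``voxel_size_override`` wins over both (with a logged
    notice).  ``swap_channels`` flips the (donor, acceptor) order for
    files acquired with the opposite channel convention — never silent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_vs = _voxel_size_from_metadata(tif)
        axes = tif.series[0].axes if tif.series else ""
    if data.ndim == 3:
        raise ValueError(
            f"{path} has a single channel; a donor+acceptor two-channel stack is required"
        )
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a (C, Z, Y, X) stack, got shape {data.shape}")
    if axes == "ZCYX":
        data = np.swapaxes(data, 0, 1)
    if data.shape[0] != 2:
        raise ValueError(f"{path} has {data.shape[0]} channels; exactly 2 are required")
    if voxel_size_override is not None:
        if meta_vs is not None and tuple(voxel_size_override) != meta_vs:
            logger.info(
                "voxel size override %s replaces metadata value %s",
                voxel_size_override,
                meta_vs,
            )
        vs = tuple(voxel_size_override)
    elif meta_vs is not None:
        vs = meta_vs
    else:
        raise ValueError(
            f"{path} carries no voxel-size metadata; pass voxel_size_override=(dz, dy, dx)"
        )
    if swap_channels:
        logger.info("channel order swapped at read time by explicit request")
        data = data[::-1]
    return ImageStack(data=data, voxel_size_um=vs)


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Write a 3-D integer label volume (0 = background) as TIFF."""
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("label volume must be 3-D (z, y, x)")
    path = Path(path)
    tifffile.imwrite(
        path, labels.astype(np.int32), ome=True, photometric="minisblack",
        metadata={"axes": "ZYX"},
    )
    return path


def read_labels(path: str | Path) -> np.ndarray:
    labels = tifffile.imread(path)
    if labels.ndim != 3:
        raise ValueError(f"{path}: label volume must be 3-D, got shape {labels.shape}")
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# Per-cell tables


def records_to_frame(records: Iterable[CellRecord]) -> pd.DataFrame:
    rows = [
        {
            "label": r.label,
            "volume_vox": r.volume_vox,
            "centroid_z_um": r.centroid_um[0],
            "centroid_y_um": r.centroid_um[1],
            "centroid_x_um": r.centroid_um[2],
            "mean_670": r.mean_670,
            "mean_720": r.mean_720,
            "ratio_720_670": r.ratio_720_670,
            "excluded_reason": r.excluded_reason,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[CellRecord]:
    return [
        CellRecord(
            label=int(row.label),
            volume_vox=int(row.volume_vox),
            centroid_um=(float(row.centroid_z_um), float(row.centroid_y_um), float(row.centroid_x_um)),
            mean_670=float(row.mean_670),
            mean_720=float(row.mean_720),
            ratio_720_670=float(row.ratio_720_670),
            excluded_reason=str(row.excluded_reason),
        )
        for row in df.itertuples()
    ]


def write_records_table(records: Sequence[CellRecord], path: str | Path) -> Path:
    """Write per-ROI measurements to CSV in the fixed column order.

    Floats are written in full repr precision so a read-back round-trips
    exactly.
    """
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")
    return path


def read_records_table(path: str | Path) -> list[CellRecord]:
    # blank numeric fields (ROIs pruned before measurement) become NaN,
    # but the excluded_reason strings are never NA-coerced
    df = pd.read_csv(path, keep_default_na=False, na_values=[""], dtype={"excluded_reason": str})
    if list(df.columns) != RECORD_COLUMNS:
        raise ValueError(f"{path}: unexpected columns {list(df.columns)}")
    return frame_to_records(df)


# ---------------------------------------------------------------------------
# Pseudo-color rendering


def render_pseudocolor(
    records: Sequence[CellRecord],
    labels: np.ndarray,
    ratio_limits: tuple[float, float],
    path: str | Path | None = None,
    cmap: str = "jet",
) -> np.ndarray:
    """Maximum-intensity projection with each retained ROI ratio-colored.

    Each retained ROI is filled with the colormap color of its 720/670
    ratio; excluded ROIs are omitted.  Returns the RGB image; when
    ``path`` is given, also saves a PNG with a color-bar scale.
    """
    lo, hi = ratio_limits
    if not lo < hi:
        raise ValueError("ratio_limits must satisfy low < high")
    labels = np.asarray(labels)
    ratio_of = {r.label: r.ratio_720_670 for r in records if r.retained}
    # MIP of the label volume restricted to retained ROIs
    keep = np.isin(labels, list(ratio_of) or [0])
    masked = np.where(keep, labels, 0)
    mip = masked.max(axis=0)
    norm = Normalize(vmin=lo, vmax=hi, clip=True)
    cm = colormaps[cmap]
    rgb = np.zeros(mip.shape + (3,), dtype=float)
    for lab, ratio in ratio_of.items():
        rgb[mip == lab] = cm(norm(ratio))[:3]
    if path is not None:
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(rgb)
        ax.set_axis_off()
        sm = plt.cm.ScalarMappable(norm=norm, cmap=cm)
        fig.colorbar(sm, ax=ax, fraction=0.046, label="720/670 ratio")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return rgb
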