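"""Per-ROI intensity and 720/670 ratio quantification, with exclusions.

For each segmented ROI the mean donor (670 nm) and acceptor (720 nm)
intensities are measured on the preprocessed stack and the FRET readout
is their ratio of means, ``mean_720 / mean_670`` — robust to dim edge
voxels, and invariant under any common positive rescaling of both
channels.  Objects whose ratio falls strictly below the autofluorescence
threshold (default 1.5) are excluded: in this biosensor's emission bands
tissue autofluorescence shows a markedly lower acceptor/donor ratio than
biosensor-expressing neurons.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CellRecord, ImageStack
from .spatial import CorrelationResult, pearson_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "measure_rois",
    "filter_by_ratio",
    "flag_border_rois",
    "ratio_scatter_summary",
]


def measure_rois(
    stack: ImageStack,
    labels: np.ndarray,
    excluded: dict[int, str] | None = None,
) -> list[CellRecord]:
    """Measure every ROI in a label volume.

    Per ROI: mean intensity of each channel over the ROI's voxels, ratio
    of means, volume, and the unweighted centroid of voxel centers in
    physical μm (the first z-plane's center at z = 0).  ROIs listed in
    ``excluded`` (e.g. removed by the opening filter) are carried through
    with their reason so the exclusion audit is complete.  An ROI with
    zero mean donor intensity cannot have a ratio and is excluded with
    reason ``"ratio"`` and a logged warning.
    """
    labels = np.asarray(labels)
    if stack.shape_zyx != labels.shape:
        raise ValueError(
            f"stack shape {stack.shape_zyx} and label shape {labels.shape} differ"
        )
    excluded = dict(excluded or {})
    present = np.unique(labels)
    present = present[present > 0]
    records: list[CellRecord] = []
    if present.size:
        donor = stack.donor.astype(np.float64)
        acceptor = stack.acceptor.astype(np.float64)
        mean_670 = ndimage.mean(donor, labels=labels, index=present)
        mean_720 = ndimage.mean(acceptor, labels=labels, index=present)
        volumes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels, present)
        centroids_vox = ndimage.center_of_mass(
            np.ones_like(labels, dtype=np.float64), labels, present
        )
        vs = np.asarray(stack.voxel_size_um)
        for lab, v, m670, m720, cv in zip(present, volumes, mean_670, mean_720, centroids_vox):
            lab = int(lab)
            reason = excluded.pop(lab, "none")
            if m670 <= 0:
                logger.warning("ROI %d has zero mean donor intensity; excluding", lab)
                ratio = math.nan
                reason = "ratio" if reason == "none" else reason
            else:
                ratio = float(m720) / float(m670)
            centroid_um = tuple(float(c) * s for c, s in zip(cv, vs))
            records.append(
                CellRecord(
                    label=lab,
                    volume_vox=int(v),
                    centroid_um=centroid_um,
                    mean_670=float(m670),
                    mean_720=float(m720),
                    ratio_720_670=ratio,
                    excluded_reason=reason,
                )
            )
    # ROIs removed before measurement (no voxels left) still get a record
    for lab, reason in sorted(excluded.items()):
        records.append(
            CellRecord(
                label=int(lab),
                volume_vox=0,
                centroid_um=(math.nan, math.nan, math.nan),
                mean_670=math.nan,
                mean_720=math.nan,
                ratio_720_670=math.nan,
                excluded_reason=reason,
            )
        )
    records.sort(key=lambda r: r.label)
    return records


def filter_by_ratio(
    records: Sequence[CellRecord], ratio_threshold: float = 1.5
) -> tuple[list[CellRecord], list[CellRecord]]:
    """Partition records at the autofluorescence ratio threshold.

    Records with ratio strictly below the threshold move to the excluded
    list with reason ``"ratio"``; a ratio exactly equal to the threshold
    is retained.  Records already excluded upstream stay excluded with
    their original reason.  The partition is exhaustive and disjoint.
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be > 0")
    retained: list[CellRecord] = []
    excluded: list[CellRecord] = []
    for r in records:
        if r.excluded_reason != "none":
            excluded.append(r)
        elif math.isnan(r.ratio_720_670) or r.ratio_720_670 < ratio_threshold:
            excluded.append(
                CellRecord(
                    label=r.label,
                    volume_vox=r.volume_vox,
                    centroid_um=r.centroid_um,
                    mean_670=r.mean_670,
                    mean_720=r.mean_720,
                    ratio_720_670=r.ratio_720_670,
                    excluded_reason="ratio",
                )
            )
        else:
            retained.append(r)
    logger.info(
        "ratio filter (threshold %g): %d retained, %d excluded",
        ratio_threshold,
        len(retained),
        len(excluded),
    )
    return retained, excluded


def flag_border_rois(
    records: Sequence[CellRecord], labels: np.ndarray
) -> list[CellRecord]:
    """Flag ROIs touching any face of the stack with reason ``"border"``.

    Border ROIs are retained by default in the pipeline; this opt-in
    filter marks them so they can be dropped when edge truncation of
    somata would bias volumes or ratios.
    """
    labels = np.asarray(labels)
    border_labels: set[int] = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            border_labels |= set(np.unique(labels[tuple(sl)]))
    border_labels.discard(0)
    out = []
    for r in records:
        if r.label in border_labels and r.excluded_reason == "none":
            out.append(
                CellRecord(
                    label=r.label,
                    volume_vox=r.volume_vox,
                    centroid_um=r.centroid_um,
                    mean_670=r.mean_670,
                    mean_720=r.mean_720,
                    ratio_720_670=r.ratio_720_670,
                    excluded_reason="border",
                )
            )
        else:
            out.append(r)
    return out


def ratio_scatter_summary(
    records: Sequence[CellRecord], alpha: float = 0.001
) -> tuple[pd.DataFrame, CorrelationResult]:
    """Expression-vs-ratio diagnostic.

    Emits per-record (mean_720, mean_670, ratio) and the Pearson
    correlation between donor intensity (biosensor expression) and the
    720/670 ratio.  An uncorrelated result supports ratio measurements
    being independent of expression level; zero ratio variance yields an
    explicit degenerate report.
    """
    rows = [
        {"label": r.label, "mean_720": r.mean_720, "mean_670": r.mean_670, "ratio": r.ratio_720_670}
        for r in records
        if r.retained
    ]
    if len(rows) < 3:
        raise ValueError(f"scatter summary needs >= 3 retained records, got {len(rows)}")
    table = pd.DataFrame(rows, columns=["label", "mean_720", "mean_670", "ratio"])
    result = pearson_correlation(table["mean_670"], table["ratio"], alpha=alpha)
    return table, result
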