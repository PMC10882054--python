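"""Expansion-microscopy synapse quantification.

Detect presynaptic (Brp) puncta as intensity local maxima with a minimum
mutual separation, binarize the postsynaptic membrane mask, and count the
puncta lying within an apposition distance of the mask, per column ROI.
All distances are in image-space (post-expansion) nanometres and honour
anisotropic voxel sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "detect_puncta",
    "binarize_mask",
    "AppositionResult",
    "count_appositions",
    "connection_histogram",
]


def detect_puncta(
    volume: np.ndarray,
    voxel_size_nm,
    min_separation_nm: float = 200.0,
    intensity_threshold: float | None = None,
) -> pd.DataFrame:
    """Local-maximum puncta detection with a minimum mutual separation.

    Candidate maxima above the intensity threshold (Otsu when not given)
    are retained greedily in descending intensity; a candidate closer than
    ``min_separation_nm`` (anisotropy-aware, nm) to an already retained
    punctum is discarded.  Ties are broken by array order, making the
    result deterministic.

    Returns a frame with voxel indices, nm coordinates (voxel centres) and
    intensities.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    if min_separation_nm <= 0:
        raise ValueError("min_separation_nm must be positive")
    spacing = np.asarray(voxel_size_nm, dtype=float)
    if intensity_threshold is None:
        intensity_threshold = float(threshold_otsu(vol))
        logger.info("auto (Otsu) intensity threshold: %.3f", intensity_threshold)

    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = (vol == ndimage.maximum_filter(vol, footprint=footprint)) & (
        vol > intensity_threshold
    )
    coords = np.argwhere(local_max)
    if len(coords) == 0:
        return pd.DataFrame(
            columns=["z", "y", "x", "z_nm", "y_nm", "x_nm", "intensity"]
        )
    intens = vol[tuple(coords.T)]
    # greedy by descending intensity, stable in array order
    order = np.lexsort(
        (coords[:, 2], coords[:, 1], coords[:, 0], -intens)
    )
    coords = coords[order]
    intens = intens[order]
    nm = (coords + 0.5) * spacing
    retained: list[int] = []
    for i in range(len(coords)):
        ok = True
        for j in retained:
            if np.linalg.norm(nm[i] - nm[j]) < min_separation_nm:
                ok = False
                break
        if ok:
            retained.append(i)
    keep = np.array(retained, dtype=int)
    return pd.DataFrame(
        {
            "z": coords[keep, 0],
            "y": coords[keep, 1],
            "x": coords[keep, 2],
            "z_nm": nm[keep, 0],
            "y_nm": nm[keep, 1],
            "x_nm": nm[keep, 2],
            "intensity": intens[keep],
        }
    ).reset_index(drop=True)


def binarize_mask(
    mask_channel: np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """Binarize the membrane channel; Otsu threshold when none is given."""
    ch = np.asarray(mask_channel, dtype=float)
    if threshold is None:
        threshold = float(threshold_otsu(ch))
        logger.info("auto (Otsu) mask threshold: %.3f", threshold)
    mask = ch > threshold
    if not mask.any():
        logger.warning("binarized mask is empty; all distances will be infinite")
    return mask


@dataclass
class AppositionResult:
    """Puncta-to-mask distances and per-ROI apposed synapse counts."""

    puncta: pd.DataFrame          # nm coords, distance_nm, roi, apposed
    roi_counts: pd.Series         # apposed count per ROI label (0 = unassigned)
    max_distance_nm: float
    thresholds: dict = field(default_factory=dict)

    @property
    def total_apposed(self) -> int:
        return int(self.puncta["apposed"].sum())


def count_appositions(
    puncta: pd.DataFrame,
    mask: np.ndarray,
    roi_labels: np.ndarray,
    voxel_size_nm,
    max_distance_nm: float = 300.0,
) -> AppositionResult:
    """Count puncta apposed to the mask, grouped by containing ROI.

    The minimum distance of each punctum to any mask voxel centre is read
    from an anisotropic Euclidean distance transform of the mask; puncta
    at distance <= ``max_distance_nm`` (inclusive) count as synapses into
    the ROI at their centre voxel, label 0 collecting puncta outside all
    ROIs.
    """
    if mask.shape != roi_labels.shape:
        raise ValueError("mask and ROI label volumes must share shape")
    spacing = np.asarray(voxel_size_nm, dtype=float)
    if mask.any():
        dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    else:
        dist = np.full(mask.shape, np.inf)

    out = puncta.copy()
    if len(out):
        vox = np.stack([out["z"], out["y"], out["x"]], axis=1).astype(int)
        out["distance_nm"] = dist[tuple(vox.T)]
        out["roi"] = roi_labels[tuple(vox.T)]
    else:
        out["distance_nm"] = pd.Series(dtype=float)
        out["roi"] = pd.Series(dtype=int)
    out["apposed"] = out["distance_nm"] <= max_distance_nm

    all_rois = np.unique(roi_labels)
    counts = (
        out[out["apposed"]].groupby("roi").size().reindex(all_rois, fill_value=0)
    )
    counts.name = "apposed_count"
    return AppositionResult(out, counts, max_distance_nm)


def connection_histogram(
    roi_counts: pd.Series, max_count: int | None = None
) -> pd.DataFrame:
    """Percent of columns making 0, 1, 2, ... apposed connections.

    The unassigned bucket (label 0) is excluded from the column tally.
    """
    cols = roi_counts[roi_counts.index != 0]
    if max_count is None:
        max_count = int(cols.max()) if len(cols) else 0
    values = np.arange(max_count + 1)
    pct = [
        100.0 * float((cols == v).sum()) / len(cols) if len(cols) else np.nan
        for v in values
    ]
    return pd.DataFrame({"n_connections": values, "percent_columns": pct})
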