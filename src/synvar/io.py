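"""Readers and writers for the pipeline's on-disk formats.

Synapse tables and annotations travel as CSV with documented headers,
volumes as multi-channel TIFF, ROI sets as integer label TIFF, generator
configs as YAML.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile
import yaml

from .filtering import SYNAPSE_COLUMNS, ConnectivityMatrix

__all__ = [
    "read_synapse_csv",
    "write_synapse_csv",
    "read_annotation_csv",
    "write_annotation_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_volume_tiff",
    "read_volume_tiff",
    "write_roi_tiff",
    "read_roi_tiff",
    "write_volume_meta",
    "read_volume_meta",
]


def read_synapse_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"pre_segment_id": str, "post_cell_id": str})
    missing = set(SYNAPSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"synapse CSV missing columns: {sorted(missing)}")
    return df[SYNAPSE_COLUMNS]


def write_synapse_csv(table: pd.DataFrame, path) -> None:
    table[SYNAPSE_COLUMNS].to_csv(path, index=False)


def read_annotation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"segment_id": str})
    if "segment_id" not in df.columns or "type_label" not in df.columns:
        raise ValueError("annotation CSV needs segment_id and type_label")
    return df


def write_annotation_csv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, index=False)


def write_matrix_csv(matrix: ConnectivityMatrix, path) -> None:
    matrix.data.rename_axis("target_cell").to_csv(path)


def read_matrix_csv(path, mode: str = "absolute") -> ConnectivityMatrix:
    data = pd.read_csv(path, index_col="target_cell")
    return ConnectivityMatrix(data, mode)


def write_volume_tiff(volume: dict, path) -> None:
    stack = np.stack([volume["puncta"], volume["mask"]]).astype(np.float32)
    tifffile.imwrite(path, stack)


def read_volume_tiff(path, voxel_size_nm, expansion_factor) -> dict:
    stack = tifffile.imread(path)
    return {
        "puncta": stack[0].astype(float),
        "mask": stack[1].astype(float),
        "voxel_size_nm": tuple(voxel_size_nm),
        "expansion_factor": float(expansion_factor),
    }


def write_roi_tiff(roi_labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, roi_labels.astype(np.int32))


def read_roi_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_volume_meta(path, voxel_size_nm, expansion_factor, **extra) -> None:
    payload = {
        "voxel_size_nm": [float(v) for v in voxel_size_nm],
        "expansion_factor": float(expansion_factor),
    }
    payload.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def read_volume_meta(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
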