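"""Column coordinates, dorsoventral assignment and presence maps.

Each analyzed target cell stands for one retinotopic column.  Its spatial
coordinate is the presynaptic site closest to the centroid of its
dendritic postsynapses; columns are split into dorsal and ventral halves
by projecting all coordinates to their best-fit plane (SVD) and drawing a
midline through the centroid along the first principal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filtering import ConnectivityMatrix

__all__ = [
    "assign_column_coordinate",
    "assign_all_coordinates",
    "dorsoventral_split",
    "presence_map",
    "patch_presence_fraction",
    "join_count_test",
]


def assign_column_coordinate(
    table: pd.DataFrame, target_cell: str
) -> np.ndarray:
    """Spatial coordinate of one column.

    Centroid of the target cell's dendritic postsynapse positions, then
    the synapse position nearest that centroid (Euclidean, ties broken by
    input order).
    """
    sub = table[
        (table["post_cell_id"] == target_cell)
        & (table["compartment"] == "dendritic")
    ]
    if sub.empty:
        raise ValueError(f"target cell {target_cell!r} has no dendritic synapses")
    pos = sub[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    centroid = pos.mean(axis=0)
    d = np.linalg.norm(pos - centroid, axis=1)
    return pos[int(np.argmin(d))].copy()


def assign_all_coordinates(table: pd.DataFrame) -> pd.DataFrame:
    """Coordinates for every target cell in the table (dendritic synapses)."""
    rows = {}
    for cell in sorted(table["post_cell_id"].unique()):
        try:
            rows[cell] = assign_column_coordinate(table, cell)
        except ValueError:
            continue
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["x_nm", "y_nm", "z_nm"]
    )


def dorsoventral_split(
    coords: pd.DataFrame, dorsal_reference: np.ndarray | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign dorsal/ventral labels by a planar SVD projection.

    The 3D coordinates are centered and projected on the top-2 right
    singular vectors; the midline runs through the 2D centroid along the
    first principal axis, so labels follow the sign of the second in-plane
    coordinate.  ``dorsal_reference`` (a 3D point) anchors the
    orientation: the half containing it is called dorsal.  Without a
    reference, the positive side of the second axis is dorsal.

    Returns the label series and the projected 2D coordinates.
    """
    pts = coords[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    center = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - center, full_matrices=False)
    if s[1] <= s[0] * 1e-9:
        raise ValueError("points are collinear; projection plane undefined")
    proj = (pts - center) @ vt[:2].T
    second = proj[:, 1]
    sign = 1.0
    if dorsal_reference is not None:
        ref2 = (np.asarray(dorsal_reference, dtype=float) - center) @ vt[:2].T
        if ref2[1] < 0:
            sign = -1.0
    labels = pd.Series(
        np.where(sign * second >= 0, "dorsal", "ventral"),
        index=coords.index,
        name="dv_label",
    )
    proj_df = pd.DataFrame(
        proj * np.array([1.0, sign]), index=coords.index, columns=["u_nm", "v_nm"]
    )
    return labels, proj_df


def presence_map(
    matrix: ConnectivityMatrix,
    coords: pd.DataFrame,
    type_label: str,
    multiplicity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-column record of one input type's presence across the eye.

    Every matrix row yields exactly one record (position, presence, and
    the number of cells of the type when multiplicities are supplied);
    rows without a coordinate are reported with NaN positions.
    """
    if type_label not in matrix.data.columns:
        raise KeyError(f"type {type_label!r} not in matrix")
    present = (matrix.data[type_label] > 0).astype(int)
    out = coords.reindex(matrix.data.index).copy()
    out["present"] = present
    if multiplicity is not None and type_label in multiplicity.columns:
        out["multiplicity"] = multiplicity[type_label].reindex(matrix.data.index)
    missing = out[["x_nm", "y_nm", "z_nm"]].isna().any(axis=1)
    out["has_coordinate"] = ~missing
    return out


def patch_presence_fraction(
    pmap: pd.DataFrame, polygon: np.ndarray | None = None
) -> float:
    """Presence fraction within a 2D polygon (x_nm, y_nm), or globally."""
    sub = pmap[pmap["has_coordinate"]]
    if polygon is not None:
        from matplotlib.path import Path

        inside = Path(np.asarray(polygon, dtype=float)).contains_points(
            sub[["x_nm", "y_nm"]].to_numpy()
        )
        sub = sub[inside]
    if len(sub) == 0:
        return float("nan")
    return float(sub["present"].mean())


def join_count_test(
    coords: pd.DataFrame,
    present: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Permutation join-count test for spatial structure of presence labels.

    The statistic is the number of nearest-neighbour pairs with matching
    presence labels.  The null distribution permutes labels over columns;
    a statistic outside the central 95% interval indicates spatial
    organization (clustered or dispersed presence).
    """
    idx = coords.index.intersection(present.index)
    pts = coords.loc[idx, ["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    labels = present.loc[idx].to_numpy(dtype=int)
    n = len(pts)
    if n < 10:
        raise ValueError("need at least 10 columns")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)

    def stat(lab):
        return int((lab == lab[nn]).sum())

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    null = np.array(
        [stat(rng.permutation(labels)) for _ in range(n_permutations)]
    )
    lo, hi = np.percentile(null, [2.5, 97.5])
    p = (1 + np.sum(null >= observed)) / (1 + n_permutations)
    return {
        "observed": observed,
        "null_low": float(lo),
        "null_high": float(hi),
        "outside_null": bool(observed < lo or observed > hi),
        "p_greater": float(p),
        "n_permutations": n_permutations,
    }
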