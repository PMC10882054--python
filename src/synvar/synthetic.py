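"""Synthetic connectomes, image volumes and calcium traces with known ground truth.

The generators emulate the statistical structure of columnar input
connectivity in the fly medulla: a small set of "core" input types present
in every retinotopic column with high synapse counts, many "variable" types
with Bernoulli presence and low counts, wide-field types contributing 0-4
cells per column, near-duplicate synapse detections, sub-threshold partners
and a two-hemisphere hexagonal column lattice.  Every planted quantity is
recorded so downstream filtering and statistics can be checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InputTypeSpec",
    "ConnectomeConfig",
    "GroundTruth",
    "generate_connectome",
    "generate_puncta_volume",
    "generate_trace_set",
    "tm9_like_config",
    "tm1_like_config",
    "TraceSet",
]


# ---------------------------------------------------------------------------
# connectome generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputTypeSpec:
    """One presynaptic input type.

    count_mean / count_sd are the per-column synapse count moments (a
    discretized normal truncated from below is used as the count model).
    ``max_cells_per_column`` > 1 marks wide-field types that can contribute
    several distinct cells to one column.  ``compartment`` is where the
    type's synapses sit on the target cell (CT1-like types target the axon
    terminal, most others the dendrite).
    """

    name: str
    presence_prob: float = 1.0
    count_mean: float = 5.0
    count_sd: float = 2.0
    max_cells_per_column: int = 1
    compartment: str = "dendritic"

    def __post_init__(self) -> None:
        if not (0.0 < self.presence_prob <= 1.0):
            raise ValueError(
                f"presence_prob must be in (0, 1], got {self.presence_prob} "
                f"for type {self.name!r}"
            )
        if self.count_mean <= 0:
            raise ValueError(f"count_mean must be > 0 for type {self.name!r}")
        if self.max_cells_per_column < 1:
            raise ValueError("max_cells_per_column must be >= 1")


def _default_core_types() -> list[InputTypeSpec]:
    # Per-column count moments of the three ubiquitous Tm9 inputs.
    return [
        InputTypeSpec("L3", 1.0, 25.0, 7.3),
        InputTypeSpec("CT1", 1.0, 15.0, 5.7, compartment="axonal"),
        InputTypeSpec("Mi4", 1.0, 13.3, 7.0),
    ]


def _default_variable_types() -> list[InputTypeSpec]:
    # Seventeen variable inputs: moderate-presence columnar types plus
    # wide-field types (Tm16/Dm12-like) with up to 4 cells per column.
    specs = [
        ("Tm16", 0.80, 7.0, 3.0, 4),
        ("Tm20", 0.55, 6.0, 2.5, 1),
        ("Dm12", 0.50, 6.5, 2.8, 4),
        ("C3", 0.45, 5.5, 2.2, 1),
        ("C2", 0.40, 5.0, 2.0, 1),
        ("Tm1", 0.35, 5.0, 2.0, 1),
        ("Tm2", 0.30, 4.5, 1.8, 1),
        ("TmY15", 0.30, 4.5, 1.8, 2),
        ("Mi13", 0.25, 4.5, 1.8, 1),
        ("Dm2", 0.25, 4.0, 1.5, 2),
        ("Tm5c", 0.20, 4.0, 1.5, 1),
        ("Mi9", 0.20, 4.0, 1.5, 1),
        ("Tm4", 0.15, 4.0, 1.5, 1),
        ("TmY10", 0.15, 4.0, 1.5, 2),
        ("Mt11", 0.12, 4.0, 1.5, 1),
        ("Tm23", 0.10, 4.0, 1.5, 1),
        ("Mi10", 0.10, 4.0, 1.5, 1),
    ]
    return [
        InputTypeSpec(n, p, m, s, c) for (n, p, m, s, c) in specs
    ]


@dataclass
class ConnectomeConfig:
    """Parameters of the synthetic columnar connectome.

    Defaults emulate the Tm9 input architecture: three core inputs with
    per-column means near 25/15/13.3 synapses and many low-count variable
    inputs, laid out on a ~5 um hexagonal column lattice mirrored across
    two hemispheres.
    """

    n_columns_per_hemisphere: int = 170
    core_types: list[InputTypeSpec] = field(default_factory=_default_core_types)
    variable_types: list[InputTypeSpec] = field(
        default_factory=_default_variable_types
    )
    duplicate_rate: float = 0.05
    subthreshold_rate: float = 0.25
    low_cleft_rate: float = 0.05
    unannotated_rate: float = 0.0
    cleft_mean: float = 100.0
    cleft_sd: float = 25.0
    cleft_floor: float = 0.0
    column_spacing_nm: float = 5000.0
    min_planted_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_columns_per_hemisphere < 1:
            raise ValueError("n_columns_per_hemisphere must be positive")
        if self.column_spacing_nm <= 0:
            raise ValueError("column_spacing_nm must be positive")
        for rate in (
            self.duplicate_rate,
            self.subthreshold_rate,
            self.low_cleft_rate,
            self.unannotated_rate,
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")

    @property
    def all_types(self) -> list[InputTypeSpec]:
        return list(self.core_types) + list(self.variable_types)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ConnectomeConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        for key in ("core_types", "variable_types"):
            payload[key] = [InputTypeSpec(**t) for t in payload[key]]
        return cls(**payload)


@dataclass
class GroundTruth:
    """Planted quantities of one synthetic connectome.

    presence / planted_counts / cell_multiplicity are column-by-type frames
    over the post-filter universe (duplicates, sub-threshold partners,
    low-cleft detections and unannotated cells excluded).
    """

    presence: pd.DataFrame
    planted_counts: pd.DataFrame
    cell_multiplicity: pd.DataFrame
    dv_label: pd.Series
    column_centers: pd.DataFrame
    n_true_synapses: int
    n_duplicates: int
    subthreshold_total: int
    unknown_total: int

    def to_json(self, path) -> None:
        payload = {
            "presence": self.presence.to_dict(),
            "planted_counts": self.planted_counts.to_dict(),
            "cell_multiplicity": self.cell_multiplicity.to_dict(),
            "dv_label": self.dv_label.to_dict(),
            "column_centers": self.column_centers.to_dict(),
            "n_true_synapses": self.n_true_synapses,
            "n_duplicates": self.n_duplicates,
            "subthreshold_total": self.subthreshold_total,
            "unknown_total": self.unknown_total,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _hex_lattice(n: int, spacing: float) -> np.ndarray:
    """Return n column centers of a wide hexagonal patch, (n, 2) in nm.

    The patch is roughly twice as wide (x) as tall (y) so its first
    principal axis is unambiguous, which keeps the dorsoventral midline
    well defined.
    """
    nx = max(2, int(np.ceil(np.sqrt(2.0 * n))))
    pts = []
    row = 0
    while len(pts) < n:
        y = row * spacing * np.sqrt(3.0) / 2.0
        x0 = (row % 2) * spacing / 2.0
        for i in range(nx):
            pts.append((x0 + i * spacing, y))
            if len(pts) >= n:
                break
        row += 1
    return np.asarray(pts, dtype=float)


def _truncated_count(rng, mean, sd, lower) -> int:
    """Discretized normal count, resampled to be >= lower."""
    for _ in range(200):
        c = int(round(rng.normal(mean, sd)))
        if c >= lower:
            return c
    return int(lower)


def _true_cleft(rng, mean, sd) -> float:
    """Cleft score for a genuine synapse; resampled to clear the 50 filter."""
    for _ in range(200):
        s = rng.normal(mean, sd)
        if s >= 51.0:
            return float(s)
    return 51.0


def _place_synapse(rng, center, sd, existing, min_sep=100.0) -> np.ndarray:
    """3D jittered position at least min_sep nm from same-pair synapses."""
    for _ in range(100):
        pos = center + rng.normal(0.0, sd, size=3)
        if not existing:
            return pos
        d = np.linalg.norm(np.asarray(existing) - pos, axis=1)
        if (d >= min_sep).all():
            return pos
    # deterministic fallback: step away from the nearest neighbour
    base = np.asarray(existing)
    pos = center + rng.normal(0.0, sd, size=3)
    while True:
        d = np.linalg.norm(base - pos, axis=1)
        if (d >= min_sep).all():
            return pos
        j = int(np.argmin(d))
        direction = pos - base[j]
        norm = np.linalg.norm(direction)
        if norm == 0:
            direction = np.array([1.0, 0.0, 0.0])
            norm = 1.0
        pos = base[j] + direction / norm * (min_sep * 1.2)


def generate_connectome(
    config: ConnectomeConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a synthetic two-hemisphere columnar connectome.

    Returns
    -------
    synapses : DataFrame
        One row per detected synapse: pre_segment_id, post_cell_id,
        x_nm, y_nm, z_nm, cleft_score, compartment.
    annotations : DataFrame
        segment_id -> type_label, hemisphere.
    truth : GroundTruth

    Notes
    -----
    Each (column, type) pair is present with its Bernoulli probability;
    present pairs contribute ``multiplicity`` distinct cells whose summed
    synapse count follows a discretized normal truncated from below at
    ``min_planted_count`` per cell.  Near-duplicate detections (jitter
    < 100 nm, slightly lower cleft score than their source), sub-threshold
    partner cells (1-2 synapses) and low-cleft detections (< 50) are
    injected on top and excluded from the planted bookkeeping.
    """
    rng = np.random.default_rng(config.seed)
    spacing = config.column_spacing_nm
    n = config.n_columns_per_hemisphere
    jitter_sd = spacing / 4.0

    lattice = _hex_lattice(n, spacing)
    type_names = [t.name for t in config.all_types]

    rows = []            # true synapse rows
    ann_rows = []
    col_ids, centers_rows = [], []
    presence = {}
    counts = {}
    multiplicity = {}
    dv = {}
    sub_total = 0
    unk_total = 0
    seg_counter = 0

    # planted dorsoventral label: the sign of the lattice's second
    # principal axis (oriented so the max-y column is dorsal), i.e. the
    # half-plane a planar SVD split recovers; invariant to the mirror
    # reflection applied to the left hemisphere
    centered = lattice - lattice.mean(axis=0)
    _, _, vt2 = np.linalg.svd(centered, full_matrices=False)
    second = centered @ vt2[1]
    if second[int(np.argmax(lattice[:, 1]))] < 0:
        second = -second
    dorsal_lattice = second >= 0

    for hemi, sign, x_off in (("R", 1.0, 2.0e5), ("L", -1.0, -2.0e5)):
        for ci in range(n):
            x2, y2 = lattice[ci]
            center = np.array([sign * x2 + x_off, y2, 0.0])
            col_id = f"Tm9_{hemi}_{ci:03d}"
            col_ids.append(col_id)
            centers_rows.append(
                {"column": col_id, "x_nm": center[0], "y_nm": center[1],
                 "z_nm": center[2], "hemisphere": hemi}
            )
            dv[col_id] = "dorsal" if dorsal_lattice[ci] else "ventral"
            presence[col_id] = {}
            counts[col_id] = {}
            multiplicity[col_id] = {}

            for spec in config.all_types:
                present = rng.random() < spec.presence_prob
                if not present:
                    presence[col_id][spec.name] = 0
                    counts[col_id][spec.name] = 0
                    multiplicity[col_id][spec.name] = 0
                    continue
                # multiplicity capped so every cell can clear the count
                # threshold without inflating the column-total moments
                min_c = config.min_planted_count
                max_eff = min(
                    spec.max_cells_per_column,
                    max(1, int(spec.count_mean // max(min_c, 1))),
                )
                m = 1 if max_eff == 1 else int(rng.integers(1, max_eff + 1))
                col_total = _truncated_count(
                    rng, spec.count_mean, spec.count_sd, min_c * m
                )
                # split the column total over cells, each >= min_c
                extra = rng.multinomial(col_total - min_c * m, [1.0 / m] * m)
                per_cell = (min_c + extra).tolist()
                total = 0
                n_annotated = 0
                for c in per_cell:
                    seg_counter += 1
                    seg_id = f"seg_{seg_counter:06d}"
                    annotate = rng.random() >= config.unannotated_rate
                    placed = []
                    for _ in range(c):
                        pos = _place_synapse(rng, center, jitter_sd, placed)
                        placed.append(pos)
                        rows.append(
                            {
                                "pre_segment_id": seg_id,
                                "post_cell_id": col_id,
                                "x_nm": pos[0],
                                "y_nm": pos[1],
                                "z_nm": pos[2],
                                "cleft_score": _true_cleft(
                                    rng, config.cleft_mean, config.cleft_sd
                                ),
                                "compartment": spec.compartment,
                            }
                        )
                    if annotate:
                        ann_rows.append(
                            {"segment_id": seg_id, "type_label": spec.name,
                             "hemisphere": hemi}
                        )
                        total += c
                        n_annotated += 1
                    else:
                        unk_total += c
                if total > 0:
                    presence[col_id][spec.name] = 1
                    counts[col_id][spec.name] = total
                    multiplicity[col_id][spec.name] = n_annotated
                else:
                    presence[col_id][spec.name] = 0
                    counts[col_id][spec.name] = 0
                    multiplicity[col_id][spec.name] = 0

            # sub-threshold partners: a tail of annotated cells each below
            # the count filter, together carrying ~subthreshold_rate of the
            # column's synapses (the unreconstructed input floor)
            if config.subthreshold_rate > 0 and config.min_planted_count > 1:
                col_true = int(sum(counts[col_id].values()))
                rate = config.subthreshold_rate
                target = rate / (1.0 - rate) * col_true
                emitted = 0
                while emitted < target:
                    seg_counter += 1
                    seg_id = f"seg_{seg_counter:06d}"
                    c = int(rng.integers(1, config.min_planted_count))
                    emitted += c
                    sub_total += c
                    placed = []
                    for _ in range(c):
                        pos = _place_synapse(rng, center, jitter_sd, placed)
                        placed.append(pos)
                        rows.append(
                            {
                                "pre_segment_id": seg_id,
                                "post_cell_id": col_id,
                                "x_nm": pos[0],
                                "y_nm": pos[1],
                                "z_nm": pos[2],
                                "cleft_score": _true_cleft(
                                    rng, config.cleft_mean, config.cleft_sd
                                ),
                                "compartment": "dendritic",
                            }
                        )
                    ann_rows.append(
                        {"segment_id": seg_id,
                         "type_label": str(
                             config.variable_types[
                                 int(rng.integers(len(config.variable_types)))
                             ].name
                         ) if config.variable_types else "tail",
                         "hemisphere": hemi}
                    )

    true_df = pd.DataFrame(rows)
    n_true = len(true_df)

    # near-duplicate detections: < 100 nm from their source, lower cleft
    dup_mask = rng.random(n_true) < config.duplicate_rate
    dup_rows = []
    for i in np.flatnonzero(dup_mask):
        src = true_df.iloc[i]
        offset = rng.normal(0.0, 1.0, size=3)
        offset *= rng.uniform(5.0, 45.0) / np.linalg.norm(offset)
        dup_rows.append(
            {
                "pre_segment_id": src["pre_segment_id"],
                "post_cell_id": src["post_cell_id"],
                "x_nm": src["x_nm"] + offset[0],
                "y_nm": src["y_nm"] + offset[1],
                "z_nm": src["z_nm"] + offset[2],
                "cleft_score": src["cleft_score"] - 0.5,
                "compartment": src["compartment"],
            }
        )

    # low-confidence detections removed by the cleft filter
    n_low = int(round(config.low_cleft_rate * n_true))
    low_rows = []
    for _ in range(n_low):
        i = int(rng.integers(n_true))
        src = true_df.iloc[i]
        low_rows.append(
            {
                "pre_segment_id": src["pre_segment_id"],
                "post_cell_id": src["post_cell_id"],
                "x_nm": src["x_nm"] + rng.normal(0, 500),
                "y_nm": src["y_nm"] + rng.normal(0, 500),
                "z_nm": src["z_nm"] + rng.normal(0, 500),
                "cleft_score": float(
                    np.clip(rng.uniform(config.cleft_floor, 49.9), 0, 49.9)
                ),
                "compartment": src["compartment"],
            }
        )

    synapses = pd.concat(
        [true_df, pd.DataFrame(dup_rows), pd.DataFrame(low_rows)],
        ignore_index=True,
    )
    # shuffle so downstream order assumptions are exercised
    perm = rng.permutation(len(synapses))
    synapses = synapses.iloc[perm].reset_index(drop=True)

    annotations = pd.DataFrame(ann_rows).drop_duplicates("segment_id")
    truth = GroundTruth(
        presence=pd.DataFrame.from_dict(presence, orient="index")[type_names],
        planted_counts=pd.DataFrame.from_dict(counts, orient="index")[type_names],
        cell_multiplicity=pd.DataFrame.from_dict(
            multiplicity, orient="index"
        )[type_names],
        dv_label=pd.Series(dv, name="dv_label"),
        column_centers=pd.DataFrame(centers_rows).set_index("column"),
        n_true_synapses=n_true,
        n_duplicates=len(dup_rows),
        subthreshold_total=sub_total,
        unknown_total=unk_total,
    )
    return synapses, annotations, truth


def tm9_like_config(seed: int = 0, n_columns: int = 170) -> ConnectomeConfig:
    """Study-condition generator: 3 moderate cores, many low-presence inputs."""
    return ConnectomeConfig(
        n_columns_per_hemisphere=n_columns, seed=seed
    )


def tm1_like_config(seed: int = 0, n_columns: int = 170) -> ConnectomeConfig:
    """Homogeneous comparison generator: one dominant input, high presence."""
    core = [
        InputTypeSpec("L2", 1.0, 100.0, 10.0),
        InputTypeSpec("L5", 1.0, 20.0, 4.0),
        InputTypeSpec("C2", 1.0, 12.0, 3.0),
    ]
    variable = [
        InputTypeSpec("Tm9", 0.95, 6.0, 2.0),
        InputTypeSpec("Mi4", 0.92, 6.0, 2.0),
        InputTypeSpec("Mi9", 0.90, 5.0, 2.0),
        InputTypeSpec("Tm4", 0.88, 5.0, 2.0),
        InputTypeSpec("Tm2", 0.85, 5.0, 2.0),
        InputTypeSpec("C3", 0.85, 4.5, 1.5),
        InputTypeSpec("Mi13", 0.82, 4.5, 1.5),
    ]
    return ConnectomeConfig(
        n_columns_per_hemisphere=n_columns,
        core_types=core,
        variable_types=variable,
        seed=seed,
    )


def subtype_configs(
    seed: int = 0, n_columns: int = 85
) -> tuple[ConnectomeConfig, ConnectomeConfig]:
    """Configs for two planted connectivity subtypes.

    One population is dominated by CT1 input, the other by Mi4, with
    otherwise identical architecture — the planted analogue of two
    GABAergic-input-defined subtypes of the same cell type.
    """

    def cores(ct1_mean: float, mi4_mean: float) -> list[InputTypeSpec]:
        return [
            InputTypeSpec("L3", 1.0, 25.0, 5.0),
            InputTypeSpec("CT1", 1.0, ct1_mean, 3.0, compartment="axonal"),
            InputTypeSpec("Mi4", 1.0, mi4_mean, 3.0),
        ]

    shared = dict(
        n_columns_per_hemisphere=n_columns,
        variable_types=_default_variable_types(),
        duplicate_rate=0.0,
        subthreshold_rate=0.0,
        low_cleft_rate=0.0,
    )
    ct1_dom = ConnectomeConfig(core_types=cores(22.0, 6.0), seed=seed, **shared)
    mi4_dom = ConnectomeConfig(
        core_types=cores(6.0, 22.0), seed=seed + 1, **shared
    )
    return ct1_dom, mi4_dom


def generate_motif_profiles(
    n_rows: int = 320,
    n_motifs: int = 4,
    n_types: int = 17,
    flip_prob: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted-partition binary presence profiles.

    Each motif is a random presence pattern over the variable input types;
    rows are split equally over motifs and each bit flipped independently
    with ``flip_prob``.  Motif patterns are resampled to differ in at
    least a quarter of the bits so the planted partition is recoverable.

    Returns the binary profile frame and the planted motif label per row.
    """
    if n_motifs < 1 or n_rows < n_motifs:
        raise ValueError("need n_rows >= n_motifs >= 1")
    rng = np.random.default_rng(seed)
    min_diff = max(1, n_types // 4)
    patterns: list[np.ndarray] = []
    while len(patterns) < n_motifs:
        cand = (rng.random(n_types) < 0.5).astype(int)
        if all((cand != p).sum() >= min_diff for p in patterns):
            patterns.append(cand)
    labels = np.repeat(np.arange(n_motifs), int(np.ceil(n_rows / n_motifs)))[
        :n_rows
    ]
    base = np.stack([patterns[c] for c in labels])
    flips = rng.random(base.shape) < flip_prob
    profiles = np.where(flips, 1 - base, base)
    cols = [f"type_{i:02d}" for i in range(n_types)]
    index = [f"col_{i:03d}" for i in range(n_rows)]
    return (
        pd.DataFrame(profiles, index=index, columns=cols),
        pd.Series(labels, index=index, name="motif"),
    )


# ---------------------------------------------------------------------------
# expansion-microscopy volume generator
# ---------------------------------------------------------------------------

def generate_puncta_volume(
    shape_voxels: tuple[int, int, int],
    voxel_size_nm: Sequence[float],
    expansion_factor: float,
    planted_puncta: Sequence[Sequence[float]],
    *,
    puncta_amplitude: float = 100.0,
    puncta_sigma_nm: float = 120.0,
    mask_tubes: Sequence[tuple[Sequence[float], Sequence[float], float]] = (),
    n_rois: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Render a two-channel ExM-like volume with planted puncta and a mask.

    Parameters
    ----------
    shape_voxels : (nz, ny, nx)
    voxel_size_nm : (z, y, x) voxel size in image-space nanometres
    planted_puncta : sequence of (z, y, x) centres in nm
    mask_tubes : sequence of (start_nm, end_nm, radius_nm) cylinders
        rendered into the membrane channel (a dendrite stand-in)
    n_rois : number of column ROIs; the volume is split into n_rois
        equal slabs along x, each one label

    Returns
    -------
    volume : dict with 'puncta', 'mask' float arrays and metadata
    roi_labels : int array, 0 = outside all ROIs
    truth : DataFrame, one row per planted punctum with its ROI label and
        true minimum distance (nm) to the rendered mask
    """
    if expansion_factor <= 0:
        raise ValueError("expansion_factor must be positive")
    vz, vy, vx = (float(v) for v in voxel_size_nm)
    if min(vz, vy, vx) <= 0:
        raise ValueError("voxel sizes must be positive")
    nz, ny, nx = shape_voxels
    extent = np.array([nz * vz, ny * vy, nx * vx])
    pts = np.asarray(planted_puncta, dtype=float).reshape(-1, 3)
    if len(pts) and ((pts < 0).any() or (pts >= extent).any()):
        raise ValueError("planted puncta must lie inside the volume")

    rng = np.random.default_rng(seed)
    zz = (np.arange(nz) + 0.5)[:, None, None] * vz
    yy = (np.arange(ny) + 0.5)[None, :, None] * vy
    xx = (np.arange(nx) + 0.5)[None, None, :] * vx

    puncta_ch = np.zeros(shape_voxels, dtype=float)
    for (pz, py, px) in pts:
        d2 = (zz - pz) ** 2 + (yy - py) ** 2 + (xx - px) ** 2
        puncta_ch += puncta_amplitude * np.exp(-d2 / (2.0 * puncta_sigma_nm**2))

    mask_ch = np.zeros(shape_voxels, dtype=bool)
    for (start, end, radius) in mask_tubes:
        a = np.asarray(start, dtype=float)
        b = np.asarray(end, dtype=float)
        ab = b - a
        L2 = float(ab @ ab)
        pz = zz - a[0]
        py = yy - a[1]
        px = xx - a[2]
        t = (pz * ab[0] + py * ab[1] + px * ab[2]) / L2 if L2 > 0 else 0.0
        t = np.clip(t, 0.0, 1.0)
        d2 = (
            (pz - t * ab[0]) ** 2
            + (py - t * ab[1]) ** 2
            + (px - t * ab[2]) ** 2
        )
        mask_ch |= d2 <= radius**2

    mask_intensity = mask_ch.astype(float) * 100.0
    if noise_sd > 0:
        puncta_ch = puncta_ch + rng.normal(0.0, noise_sd, shape_voxels)
        mask_intensity = mask_intensity + rng.normal(0.0, noise_sd, shape_voxels)

    roi_labels = np.zeros(shape_voxels, dtype=np.int32)
    edges = np.linspace(0, nx, n_rois + 1).astype(int)
    for r in range(n_rois):
        roi_labels[:, :, edges[r]:edges[r + 1]] = r + 1

    # true distances: exhaustive against mask voxel centres
    truth_rows = []
    mask_coords = np.argwhere(mask_ch)
    mask_nm = (mask_coords + 0.5) * np.array([vz, vy, vx])
    for (pz_, py_, px_) in pts:
        vox = np.minimum(
            (np.array([pz_, py_, px_]) / np.array([vz, vy, vx])).astype(int),
            np.array(shape_voxels) - 1,
        )
        if len(mask_nm):
            d = float(
                np.sqrt(
                    ((mask_nm - np.array([pz_, py_, px_])) ** 2).sum(axis=1)
                ).min()
            )
            if mask_ch[tuple(vox)]:
                d = 0.0
        else:
            d = np.inf
        truth_rows.append(
            {
                "z_nm": pz_,
                "y_nm": py_,
                "x_nm": px_,
                "roi": int(roi_labels[tuple(vox)]),
                "true_distance_nm": d,
            }
        )

    volume = {
        "puncta": puncta_ch,
        "mask": mask_intensity,
        "voxel_size_nm": (vz, vy, vx),
        "expansion_factor": float(expansion_factor),
    }
    return volume, roi_labels, pd.DataFrame(
        truth_rows, columns=["z_nm", "y_nm", "x_nm", "roi", "true_distance_nm"]
    )


# ---------------------------------------------------------------------------
# calcium trace generator
# ---------------------------------------------------------------------------

@dataclass
class TraceSet:
    """ROI x time fluorescence with acquisition metadata.

    epochs are (label, start_s, end_s) within one trial; n_trials equal-
    length trials are concatenated along time.
    """

    F: np.ndarray
    sampling_rate: float
    epochs: list[tuple[str, float, float]] = field(default_factory=list)
    n_trials: int = 1

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("F must be ROI x time")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isfinite(self.F).all():
            raise ValueError("fluorescence values must be finite")

    @property
    def n_rois(self) -> int:
        return self.F.shape[0]

    @property
    def n_samples(self) -> int:
        return self.F.shape[1]


def generate_trace_set(
    n_rois_per_cluster: int,
    templates: np.ndarray,
    *,
    amplitude_sd: float = 0.1,
    noise_sd: float = 0.05,
    sampling_rate: float = 10.0,
    epochs: Sequence[tuple[str, float, float]] = (),
    seed: int = 0,
) -> tuple[TraceSet, pd.Series]:
    """ROI traces as amplitude x cluster template + Gaussian noise.

    Returns the TraceSet and the planted cluster label per ROI.
    """
    templates = np.atleast_2d(np.asarray(templates, dtype=float))
    if templates.size == 0 or templates.shape[0] < 1:
        raise ValueError("at least one template required")
    rng = np.random.default_rng(seed)
    k, T = templates.shape
    traces, labels = [], []
    for c in range(k):
        for _ in range(n_rois_per_cluster):
            amp = max(0.1, rng.normal(1.0, amplitude_sd))
            traces.append(amp * templates[c] + rng.normal(0.0, noise_sd, T))
            labels.append(c)
    ts = TraceSet(
        np.asarray(traces), sampling_rate=sampling_rate, epochs=list(epochs)
    )
    return ts, pd.Series(labels, name="cluster")
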