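"""Synapse-table quality filters and connectivity-matrix construction.

The pipeline order is fixed: cleft-score filter -> redundancy removal ->
per-cell aggregation -> partner-count threshold -> matrix -> presence
filter.  Every stage is idempotent on its own output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = "UNKNOWN"

SYNAPSE_COLUMNS = [
    "pre_segment_id",
    "post_cell_id",
    "x_nm",
    "y_nm",
    "z_nm",
    "cleft_score",
    "compartment",
]

__all__ = [
    "UNKNOWN",
    "SYNAPSE_COLUMNS",
    "AggregatedCounts",
    "ConnectivityMatrix",
    "filter_by_cleft_score",
    "deduplicate_synapses",
    "aggregate_counts",
    "apply_partner_threshold",
    "build_connectivity_matrix",
    "filter_by_presence",
    "run_pipeline",
]


def filter_by_cleft_score(table: pd.DataFrame, min_score: float = 50.0) -> pd.DataFrame:
    """Keep synapses whose detection confidence (cleft score) is >= min_score.

    The boundary is inclusive; row order is preserved.
    """
    return table[table["cleft_score"] >= min_score].copy()


def deduplicate_synapses(table: pd.DataFrame, radius_nm: float = 100.0) -> pd.DataFrame:
    """Remove redundant detections of the same connection.

    Within each (pre-segment, post-cell) pair, synapses closer than
    ``radius_nm`` to an already-retained synapse are dropped.  Retention is
    greedy in descending cleft score, ties broken by input order, which
    keeps the most confident detection of each site and is idempotent.
    """
    if radius_nm < 0:
        raise ValueError("radius_nm must be non-negative")
    if table.empty:
        return table.copy()
    keep_mask = np.ones(len(table), dtype=bool)
    pos = table[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    scores = table["cleft_score"].to_numpy(dtype=float)
    for _, idx in table.groupby(
        ["pre_segment_id", "post_cell_id"], sort=False
    ).indices.items():
        if len(idx) < 2:
            continue
        # stable sort: descending score, ascending input order
        order = idx[np.lexsort((idx, -scores[idx]))]
        retained: list[int] = []
        for i in order:
            p = pos[i]
            ok = True
            for j in retained:
                if np.linalg.norm(p - pos[j]) < radius_nm:
                    ok = False
                    break
            if ok:
                retained.append(i)
            else:
                keep_mask[i] = False
    return table[keep_mask].copy()


@dataclass
class AggregatedCounts:
    """Synapse counts aggregated per input cell and per input type.

    cell_counts : long frame (post_cell_id, pre_segment_id, type_label,
        count); unannotated segments carry the UNKNOWN label.
    type_counts : wide frame, target cells x input types.
    multiplicity : wide frame, number of distinct input cells of each type
        with a nonzero count.
    """

    cell_counts: pd.DataFrame
    type_counts: pd.DataFrame
    multiplicity: pd.DataFrame
    hemisphere: pd.Series | None = None
    min_synapses: int | None = None

    @property
    def total_synapses(self) -> int:
        return int(self.cell_counts["count"].sum())


def _pivot(cell_counts: pd.DataFrame, targets) -> tuple[pd.DataFrame, pd.DataFrame]:
    nonzero = cell_counts[cell_counts["count"] > 0]
    type_counts = (
        nonzero.pivot_table(
            index="post_cell_id",
            columns="type_label",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(targets, fill_value=0)
        .astype(int)
    )
    multiplicity = (
        nonzero.pivot_table(
            index="post_cell_id",
            columns="type_label",
            values="pre_segment_id",
            aggfunc="nunique",
            fill_value=0,
        )
        .reindex(targets, fill_value=0)
        .reindex(columns=type_counts.columns, fill_value=0)
        .astype(int)
    )
    type_counts.columns.name = None
    multiplicity.columns.name = None
    return type_counts, multiplicity


def aggregate_counts(
    table: pd.DataFrame, annotations: pd.DataFrame
) -> AggregatedCounts:
    """Count synapses per (target cell, input cell) and per (target, type).

    Segments without an annotation are mapped to UNKNOWN, never dropped.
    """
    ann = annotations.drop_duplicates("segment_id").set_index("segment_id")
    cell = (
        table.groupby(["post_cell_id", "pre_segment_id"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    cell["type_label"] = (
        cell["pre_segment_id"].map(ann["type_label"]).fillna(UNKNOWN)
    )
    targets = sorted(table["post_cell_id"].unique())
    type_counts, multiplicity = _pivot(cell, targets)

    hemi = None
    if "hemisphere" in ann.columns:
        hemi_per_target = (
            cell.assign(h=cell["pre_segment_id"].map(ann["hemisphere"]))
            .dropna(subset=["h"])
            .groupby("post_cell_id")["h"]
            .agg(lambda s: s.mode().iloc[0])
        )
        hemi = hemi_per_target.reindex(targets)
    return AggregatedCounts(cell, type_counts, multiplicity, hemisphere=hemi)


def apply_partner_threshold(
    counts: AggregatedCounts, min_synapses: int = 3
) -> AggregatedCounts:
    """Zero out input cells below the partner-count threshold.

    The threshold acts per presynaptic segment (cell), before any type
    aggregation: cells contributing fewer than ``min_synapses`` synapses
    are set to zero, and type totals are recomputed from the surviving
    cells.
    """
    if min_synapses < 1:
        raise ValueError("min_synapses must be >= 1")
    cell = counts.cell_counts.copy()
    cell.loc[cell["count"] < min_synapses, "count"] = 0
    targets = counts.type_counts.index
    type_counts, multiplicity = _pivot(cell, targets)
    type_counts = type_counts.reindex(
        columns=counts.type_counts.columns.union(type_counts.columns),
        fill_value=0,
    )
    multiplicity = multiplicity.reindex(columns=type_counts.columns, fill_value=0)
    return AggregatedCounts(
        cell, type_counts, multiplicity,
        hemisphere=counts.hemisphere, min_synapses=min_synapses,
    )


@dataclass
class ConnectivityMatrix:
    """Target cells (rows) x input cell types (columns).

    mode 'absolute' holds integer synapse counts, 'relative' holds
    per-row fractions of the row's total count (including UNKNOWN in the
    denominator), 'binary' holds presence indicators.
    """

    data: pd.DataFrame
    mode: str
    hemisphere: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def drop_unknown(self) -> "ConnectivityMatrix":
        cols = [c for c in self.data.columns if c != UNKNOWN]
        return ConnectivityMatrix(
            self.data[cols], self.mode, self.hemisphere, dict(self.meta)
        )

    @property
    def types(self) -> list[str]:
        return list(self.data.columns)


def build_connectivity_matrix(
    counts: AggregatedCounts, mode: str = "absolute"
) -> ConnectivityMatrix:
    """Assemble the connectivity matrix from thresholded counts.

    Relative mode divides each row by its full post-threshold synapse
    total (UNKNOWN included), so removing rare types later does not
    inflate the remaining fractions; zero-total rows become all-zero with
    a warning.  Binary mode is the indicator of count > 0.
    """
    if mode not in {"absolute", "relative", "binary"}:
        raise ValueError(f"unknown mode {mode!r}")
    abs_df = counts.type_counts
    if mode == "absolute":
        data = abs_df.copy()
    elif mode == "binary":
        data = (abs_df > 0).astype(int)
    else:
        totals = abs_df.sum(axis=1).astype(float)
        zero = totals == 0
        if zero.any():
            logger.warning(
                "%d rows have zero total synapses; relative rows set to 0",
                int(zero.sum()),
            )
            totals[zero] = 1.0
        data = abs_df.div(totals, axis=0)
    meta = {"min_synapses": counts.min_synapses}
    return ConnectivityMatrix(data, mode, counts.hemisphere, meta)


def filter_by_presence(
    matrix: ConnectivityMatrix, min_fraction: float = 0.05
) -> ConnectivityMatrix:
    """Drop input types connected in fewer than ``min_fraction`` of columns.

    Presence of a type in a row means count > 0; the cut is inclusive
    (a type present in exactly the minimum fraction is retained).  The
    UNKNOWN column, when present, is always retained so relative rows keep
    their denominators interpretable.
    """
    frac = (matrix.data > 0).mean(axis=0)
    keep = [
        c
        for c in matrix.data.columns
        if c == UNKNOWN or frac[c] >= min_fraction
    ]
    meta = dict(matrix.meta)
    meta["presence_cut"] = min_fraction
    return ConnectivityMatrix(matrix.data[keep], matrix.mode, matrix.hemisphere, meta)


def run_pipeline(
    table: pd.DataFrame,
    annotations: pd.DataFrame,
    *,
    min_cleft: float = 50.0,
    dedup_nm: float = 100.0,
    min_synapses: int = 3,
    presence_cut: float = 0.05,
    mode: str = "absolute",
) -> tuple[ConnectivityMatrix, AggregatedCounts, pd.DataFrame]:
    """Full filtering pipeline in the canonical order.

    Returns the presence-filtered matrix, the thresholded counts, and the
    post-dedup synapse table.
    """
    filtered = filter_by_cleft_score(table, min_cleft)
    deduped = deduplicate_synapses(filtered, dedup_nm)
    agg = aggregate_counts(deduped, annotations)
    agg = apply_partner_threshold(agg, min_synapses)
    matrix = build_connectivity_matrix(agg, mode)
    matrix = filter_by_presence(matrix, presence_cut)
    return matrix, agg, deduped
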