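#!/usr/bin/env python
"""Filter the synapse table and build the connectivity matrices.

Reads results/data/ written by 01_simulate_connectome.py, applies the
canonical pipeline (cleft score >= 50, 100-nm redundancy removal, >= 3
synapses per partner cell, >= 5% column-presence cut) and writes the
absolute, relative and binary connectivity matrices.
"""

import argparse
from pathlib import Path

from synvar.filtering import UNKNOWN, build_connectivity_matrix, filter_by_presence, run_pipeline
from synvar.io import read_annotation_csv, read_synapse_csv, write_matrix_csv


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--min-cleft", type=float, default=50.0)
    ap.add_argument("--dedup-nm", type=float, default=100.0)
    ap.add_argument("--min-synapses", type=int, default=3)
    ap.add_argument("--presence-cut", type=float, default=0.05)
    args = ap.parse_args()

    synapses = read_synapse_csv(args.data / "synapses.csv")
    annotations = read_annotation_csv(args.data / "annotations.csv")
    matrix, agg, deduped = run_pipeline(
        synapses,
        annotations,
        min_cleft=args.min_cleft,
        dedup_nm=args.dedup_nm,
        min_synapses=args.min_synapses,
        presence_cut=args.presence_cut,
    )
    args.out.mkdir(parents=True, exist_ok=True)
    write_matrix_csv(matrix, args.out / "matrix_absolute.csv")
    for mode in ("relative", "binary"):
        m = filter_by_presence(
            build_connectivity_matrix(agg, mode), args.presence_cut
        )
        write_matrix_csv(m, args.out / f"matrix_{mode}.csv")
    if matrix.hemisphere is not None:
        matrix.hemisphere.rename("hemisphere").to_csv(
            args.out / "hemispheres.csv"
        )

    counts = matrix.data.drop(columns=[UNKNOWN], errors="ignore")
    per_col = agg.type_counts.sum(axis=1)
    print(f"{len(deduped)} synapses survive cleft + redundancy filters")
    print(f"{counts.shape[0]} columns x {counts.shape[1]} retained input types")
    print(f"synapses per column (identified): {per_col.mean():.1f} "
          f"+/- {per_col.std():.1f}")
    top = counts.mean().sort_values(ascending=False).head(4)
    print("strongest inputs (mean synapses/column):")
    for name, val in top.items():
        print(f"  {name}: {val:.1f}")


if __name__ == "__main__":
    main()
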