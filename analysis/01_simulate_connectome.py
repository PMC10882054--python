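#!/usr/bin/env python
"""Simulate the study-scale synthetic connectome and write it to disk.

Generates two mirrored optic-lobe hemispheres of 170 columns each with the
default input architecture (3 core types near 25/15/13.3 synapses per
column, 17 variable types, near-duplicate detections, a sub-threshold
partner floor and low-confidence detections), then writes the synapse
table, cell annotations, generator config and ground truth under
results/data/.
"""

import argparse
from pathlib import Path

from synvar.io import write_annotation_csv, write_synapse_csv
from synvar.synthetic import ConnectomeConfig, generate_connectome


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = ConnectomeConfig(n_columns_per_hemisphere=170, seed=args.seed)
    synapses, annotations, truth = generate_connectome(cfg)

    write_synapse_csv(synapses, args.out / "synapses.csv")
    write_annotation_csv(annotations, args.out / "annotations.csv")
    cfg.to_yaml(args.out / "config.yaml")
    truth.to_json(args.out / "ground_truth.json")
    truth.column_centers.to_csv(args.out / "column_centers.csv")
    truth.dv_label.to_csv(args.out / "dv_labels_true.csv")

    print(f"columns: {len(truth.column_centers)}")
    print(f"detected synapses written: {len(synapses)}")
    print(f"planted (post-filter) synapses: {truth.n_true_synapses}")
    print(f"  of which duplicates injected: {truth.n_duplicates}")
    print(f"  sub-threshold floor synapses: {truth.subthreshold_total}")
    print(f"outputs in {args.out}/")


if __name__ == "__main__":
    main()
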