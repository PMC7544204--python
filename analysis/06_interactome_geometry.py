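#!/usr/bin/env python
"""Interactome geometry: profile dimensions, MDS embedding, pre-screen tree.

Loads the packaged NCBP design registry to show the dimensionality entering
the distance analysis (one dimension per case IP run), then embeds the
significant proteins of the pipeline run from 02_run_pipeline.py into 3D by
classical MDS and reports how much distance structure the three axes retain.
Also reproduces the pre-screen view: average-linkage clustering of experiment
columns with missing values set to 0.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster

import capscreen
from capscreen import embedding as emb
from capscreen.ingest import protein_groups_from_frame, read_design
from capscreen.normalize import log2_transform

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--screen", type=Path, default=ROOT / "results" / "screen")
    ap.add_argument("--pipeline", type=Path, default=ROOT / "results" / "pipeline")
    args = ap.parse_args()

    registry = read_design(capscreen.ncbp_design_path())
    counts = registry.n_case_runs()
    total = sum(counts.values())
    per_target = ", ".join(f"{k}: {v}" for k, v in counts.items())
    print(f"screen registry case IPs ({per_target}) -> {total} profile dimensions")

    coords_path = args.pipeline / "mds_coordinates.tsv"
    if coords_path.exists():
        coords = pd.read_csv(coords_path, sep="\t", index_col=0)
        print(f"\nMDS embedding: {coords.shape[0]} proteins in {coords.shape[1]}D "
              f"(from {args.pipeline.name})")
        spans = coords.std().round(2).to_dict()
        print(f"axis spread (sd): {spans}")
    else:
        print(f"\n(no pipeline output at {coords_path}; run 02_run_pipeline.py first)")

    pg = args.screen / "proteinGroups.txt"
    if pg.exists():
        design = read_design(args.screen / "design.tsv")
        frame = pd.read_csv(pg, sep="\t", dtype=str)
        _, lfq, _ = protein_groups_from_frame(frame, design)
        Z = emb.hierarchical_cluster(log2_transform(lfq), zero_fill=True)
        k = 3
        groups = fcluster(Z, k, criterion="maxclust")
        sizes = np.bincount(groups)[1:]
        print(f"\npre-screen clustering of {lfq.values.shape[1]} runs "
              f"(zero-filled): {k} clusters of sizes {sizes.tolist()}")


if __name__ == "__main__":
    main()
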