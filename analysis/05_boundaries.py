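#!/usr/bin/env python
"""Boundary-quality scores for the synthetic region map.

Generates a small population of 3-compartment skeletons (some clean,
some deliberately weaving back and forth across one boundary), scores
every region boundary by excess crossings per unit area, and writes
boundary_scores.csv.  The weaving population should single out its
boundary as the poorly drawn one.
"""

from pathlib import Path

import pandas as pd

import connkit as ck
from connkit.boundaries import scores_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def weaving_skeleton(roi_a, roi_b, n_weaves, seed):
    """Unbranched skeleton whose label sequence alternates between two
    regions ``n_weaves`` times (2·n_weaves boundary crossings)."""
    labels = [roi_a] * 3
    for _ in range(n_weaves):
        labels += [roi_b] * 2 + [roi_a] * 2
    n = len(labels)
    nodes = pd.DataFrame({
        "node_id": range(1, n + 1), "struct_type": [0] * n,
        "x": [2.0 * i for i in range(n)], "y": [0.0] * n, "z": [0.0] * n,
        "radius": [0.4] * n, "parent_id": [-1] + list(range(1, n)),
        "label": labels})
    return ck.Skeleton(nodes)


def main():
    # clean skeletons: one crossing per boundary each
    skels = [ck.generate_skeleton(3, 25, 120.0, (0.1, 1.0), seed=s)
             for s in range(8)]
    # a population that recrosses the R1/R2 boundary repeatedly
    skels += [weaving_skeleton("R1", "R2", n_weaves=4, seed=s)
              for s in range(4)]
    areas = pd.DataFrame({
        "roi_a": ["R1", "R2"], "roi_b": ["R2", "R3"],
        "area_um2": [50.0, 50.0]})
    table = scores_table(ck.boundary_scores(skels, areas))
    table.to_csv(RESULTS / "boundary_scores.csv", index=False)
    print(table.to_string(index=False))
    worst = table.loc[table["excess_per_area"].idxmax()]
    print(f"\nworst boundary: {worst.roi_a}/{worst.roi_b} "
          f"({worst.excess_per_area:.3f} excess crossings per um^2)")


if __name__ == "__main__":
    main()
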