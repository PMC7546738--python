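#!/usr/bin/env python
"""Per-region network statistics and path-length curves.

For each region of the synthetic connectome: neuron/edge counts, mean
partner count, diameter, strength means split by reciprocity, the
reciprocal fraction and mean hop distance; plus the cumulative fraction
of ordered pairs connected versus interneurons required, per synapse
threshold.  Writes compartment_stats.csv and path_curves.csv.
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd

import connkit as ck

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"


def main():
    g = ck.load_connectome(DATA / "nodes.csv", DATA / "edges.csv",
                           roi_counts_path=DATA / "roi_counts.csv",
                           edge_roi_path=DATA / "edge_roi.csv")
    rows = [asdict(ck.compartment_summary(g, region="all"))]
    for roi in sorted(g.regions):
        sub = ck.restrict_to_roi(g, roi)
        if sub.n_neurons:
            rows.append(asdict(ck.compartment_summary(sub, region=roi)))
    stats = pd.DataFrame(rows)
    stats.to_csv(RESULTS / "compartment_stats.csv", index=False)
    print(stats[["region", "n_neurons", "n_connections", "k_avg", "diameter",
                 "str_avg", "frac_recip", "avg_dist"]].round(3).to_string(index=False))

    curves = ck.path_length_curve(g, [1, 3, 5, 10, 20])
    crows = [{"threshold": c.threshold, "n_interneurons": k, "cum_fraction": f}
             for c in curves for k, f in c.points]
    pd.DataFrame(crows).to_csv(RESULTS / "path_curves.csv", index=False)
    for c in curves:
        direct = c.points[0][1] if c.points else 0.0
        last = c.points[-1][1] if c.points else 0.0
        print(f"threshold {c.threshold:>2}: {direct:.1%} of pairs directly "
              f"connected, {last:.1%} connected overall")


if __name__ == "__main__":
    main()
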