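#!/usr/bin/env python
"""Generate the synthetic study connectome and skeletons.

Writes the flat-file dataset every later stage reads: an ellipsoid-body-
like connectome (300 neurons, pairwise connection probability 0.19,
power-law synapse counts with cutoff, reciprocity excess) carrying a
planted 25-cell clique and a planted overseer over a 25-cell type, plus
a 3-compartment skeleton, under results/data/.
"""

import json
from pathlib import Path

import connkit as ck
from connkit.synth import write_simulation

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main():
    cfg = ck.GeneratorConfig(n_neurons=300, seed=SEED,
                             type_plan=[("KC_like", 25), ("bg_typed", 25)])
    paths = write_simulation(
        OUT, cfg,
        clique=dict(type_name="ER4d_like", n_cells=25, mean_strength=5.0),
        overseer=dict(target_type="KC_like", n_overseers=1,
                      coverage_frac=1.0, direction="both"),
        skeleton=dict(n_regions=3, nodes_per_region=40,
                      neurite_length_um=150.0, radius_um_range=(0.1, 1.0)),
    )
    g = ck.load_connectome(paths["nodes"], paths["edges"],
                           roi_counts_path=paths["roi_counts"],
                           edge_roi_path=paths["edge_roi"])
    print(f"wrote synthetic connectome to {OUT}")
    print(f"  neurons: {g.n_neurons}, edges: {g.n_edges}, "
          f"regions: {sorted(g.regions)}")
    print(f"  planted: 25-cell clique 'ER4d_like' (600 ordered pairs), "
          f"1 overseer over 'KC_like'")


if __name__ == "__main__":
    main()
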