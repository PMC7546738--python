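#!/usr/bin/env python
"""Passive electrical response of the multi-compartment skeleton.

Builds the truncated-cone cable model of the 3-compartment skeleton,
computes region-to-region delay and amplitude matrices from sampled
synapse-site pairs, compares the matrix model's residual error against a
single-scalar model, and sweeps the 3x3 grid of axial and membrane
resistances.  Writes response_matrices.json, response_pairs.csv and
parameter_sweep.csv.
"""

import json
from pathlib import Path

import pandas as pd

import connkit as ck
from connkit.cable import DEFAULT_RA_VALUES, DEFAULT_RM_VALUES

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"


def site_maps(skel, n_each=6):
    by_region = {}
    for n, l in skel.labels().items():
        if l:
            by_region.setdefault(l, []).append(n)
    ins = {r: v[:n_each] for r, v in by_region.items()}
    outs = {r: v[n_each:2 * n_each] for r, v in by_region.items()}
    return ins, outs


def main():
    skel = ck.read_swc(DATA / "skeleton.swc", DATA / "labels.tsv")
    cable = ck.build_cable(skel, ck.CableParameters())
    ins, outs = site_maps(skel)
    m = ck.compartment_matrices(cable, ins, outs, n_sample=5, seed=1)

    print("mean delay (ms), input region x output region:")
    print(m.delay_matrix.round(2).to_string())
    print("mean amplitude (mV):")
    print(m.amplitude_matrix.round(3).to_string())
    print(f"delay residual SD: matrix {m.delay_sd_matrix:.3f} ms vs "
          f"scalar {m.delay_sd_scalar:.3f} ms")
    print(f"amplitude residual SD: matrix {m.amplitude_sd_matrix:.3f} mV vs "
          f"scalar {m.amplitude_sd_scalar:.3f} mV")

    m.pairs.to_csv(RESULTS / "response_pairs.csv", index=False)
    (RESULTS / "response_matrices.json").write_text(json.dumps({
        "regions": m.regions,
        "delay_ms": m.delay_matrix.values.tolist(),
        "amplitude_mv": m.amplitude_matrix.values.tolist(),
        "delay_sd_matrix": m.delay_sd_matrix,
        "delay_sd_scalar": m.delay_sd_scalar,
        "amplitude_sd_matrix": m.amplitude_sd_matrix,
        "amplitude_sd_scalar": m.amplitude_sd_scalar,
    }, indent=1))

    models = ck.parameter_sweep(skel, ins, outs, n_sample=3, seed=1)
    rows = []
    for (Ra, Rm), model in models.items():
        within = [model.delay_matrix.loc[r, r] for r in model.regions]
        cross = [model.delay_matrix.loc[a, b] for a in model.regions
                 for b in model.regions if a != b]
        rows.append({"Ra_ohm_m": Ra, "Rm_ohm_m2": Rm,
                     "mean_within_delay_ms": sum(within) / len(within),
                     "mean_cross_delay_ms": sum(cross) / len(cross),
                     "mean_amplitude_mv": model.amplitude_matrix.mean().mean()})
    sweep = pd.DataFrame(rows)
    sweep.to_csv(RESULTS / "parameter_sweep.csv", index=False)
    sep = (sweep["mean_cross_delay_ms"] > sweep["mean_within_delay_ms"]).all()
    print(f"\nsweep over Ra {DEFAULT_RA_VALUES} x Rm {DEFAULT_RM_VALUES}: "
          f"within/cross delay separation holds in all 9 cases: {sep}")


if __name__ == "__main__":
    main()
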