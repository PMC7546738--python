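"""Boundary-quality scoring for brain-region maps.

For each boundary between two adjacent regions, count how often traced
neurons cross it.  A neuron crossing once contributes nothing — such
crossings are inevitable wherever the boundary is drawn — but a neuron
crossing n times contributes n−1 "excess" crossings.  The score is total
excess normalized by the boundary's surface area (μm²); boundaries with
high excess per area are candidates for redefinition, as they likely cut
through functionally coherent neuropil.

Boundary areas are an input (measured from the volume segmentation
upstream); crossings are counted on skeleton edges whose endpoint labels
are the two regions, so shared trunks are counted once regardless of how
many root-to-leaf paths pass through them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .core import Skeleton

__all__ = ["BoundaryScore", "neuron_crossings", "boundary_scores"]


@dataclass
class BoundaryScore:
    roi_a: str
    roi_b: str
    area_um2: float
    crossings: int
    n_neurons: int       # distinct neurons with >=1 crossing
    excess: int          # crossings - n_neurons
    excess_per_area: float


def neuron_crossings(skel: Skeleton, roi_a: str, roi_b: str) -> int:
    """Number of tree edges of ``skel`` whose endpoint labels are
    {roi_a, roi_b} (in either order).  Edges touching a third region do
    not count; an unlabeled endpoint paired with a label in {roi_a,
    roi_b} is an error (the crossing status would be ambiguous)."""
    labels = skel.labels()
    pair = {roi_a, roi_b}
    count = 0
    for u, v in skel.edge_list():
        lu, lv = labels[u], labels[v]
        if {lu, lv} == pair:
            count += 1
        elif ("" in (lu, lv)) and (lu in pair or lv in pair) and lu != lv:
            raise ValueError(
                f"unlabeled node on a potential {roi_a}/{roi_b} crossing "
                f"edge ({u}, {v})")
    return count


def boundary_scores(skeletons, areas: pd.DataFrame) -> list[BoundaryScore]:
    """Score every boundary in the ``areas`` table.

    ``areas`` columns: roi_a, roi_b, area_um2.  Non-positive areas are
    errors.  Crossing counts are summed over ``skeletons``; neurons whose
    labels never touch a listed boundary simply contribute zero.
    """
    scores = []
    for row in areas.itertuples():
        a, b, area = str(row.roi_a), str(row.roi_b), float(row.area_um2)
        if area <= 0:
            raise ValueError(f"boundary ({a}, {b}) has non-positive area {area}")
        total = 0
        n_neurons = 0
        for skel in skeletons:
            c = neuron_crossings(skel, a, b)
            total += c
            if c > 0:
                n_neurons += 1
        scores.append(BoundaryScore(
            roi_a=a, roi_b=b, area_um2=area, crossings=total,
            n_neurons=n_neurons, excess=total - n_neurons,
            excess_per_area=(total - n_neurons) / area))
    return scores


def scores_table(scores) -> pd.DataFrame:
    """Source-data-style table: boundary pair, area, crossings, distinct
    neurons, excess per area."""
    return pd.DataFrame([{
        "roi_a": s.roi_a, "roi_b": s.roi_b, "area_um2": s.area_um2,
        "crossings": s.crossings, "n_neurons": s.n_neurons,
        "excess": s.excess, "excess_per_area": s.excess_per_area,
    } for s in scores])
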