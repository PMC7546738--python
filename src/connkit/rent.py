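"""Rent's-rule analysis of brain compartments.

Rent's rule is the empirical observation that in tightly packed
computing systems, external connectivity scales as a power law of
contained computation: Pins = a · (computation)^b, with the exponent b
in roughly 0.5–0.7 when packing dominates the design.  For a brain
compartment, computation is measured as the number of contained T-bars
(presynaptic sites) and the pin count as the number of neurons with at
least one synapse both inside and outside the compartment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import ConnectomeGraph

__all__ = ["RentPoint", "RentFit", "rent_point", "fit_rent", "classify_rent"]

PACKING_RANGE = (0.5, 0.7)


@dataclass
class RentPoint:
    region: str
    pins: int          # neurons with >=1 synapse inside AND >=1 outside
    computation: int   # T-bars (presynaptic sites) inside the region


@dataclass
class RentFit:
    a: float
    b: float
    r_squared: float
    residuals: np.ndarray   # per-point log-space residuals
    b_in_theory_range: bool  # exponent within the theoretical [0, 1]


def rent_point(g: ConnectomeGraph, roi: str,
               computation: str = "tbars") -> RentPoint:
    """One Rent point for ``roi``.

    A neuron counts as a pin when it has at least one synapse (pre or
    post) inside the region and at least one outside.  ``computation``
    selects the internal-computation measure: ``tbars`` (presynaptic
    count, the default), ``psds`` (postsynaptic count) or ``pairs``
    (unique connection pairs with synapses in the region) — the
    alternatives give very similar fits and are provided for comparison.
    """
    if roi not in g.regions:
        raise KeyError(f"unknown region {roi!r}")
    pins = 0
    tbars = psds = 0
    for _, d in g.nx.nodes(data=True):
        rc = d["roi_counts"]
        inside = sum(rc.get(roi, (0, 0)))
        outside = sum(sum(v) for r, v in rc.items() if r != roi)
        if inside >= 1 and outside >= 1:
            pins += 1
        pre, post = rc.get(roi, (0, 0))
        tbars += pre
        psds += post
    if computation == "tbars":
        comp = tbars
    elif computation == "psds":
        comp = psds
    elif computation == "pairs":
        comp = sum(1 for _, _, _, rw in g.edges() if rw.get(roi, 0) > 0)
    else:
        raise ValueError(f"unknown computation measure {computation!r}")
    return RentPoint(region=roi, pins=pins, computation=comp)


def fit_rent(points) -> RentFit:
    """Ordinary least squares of log(pins) on log(computation):
    a = exp(intercept), b = slope.  Points with zero pins or computation
    are excluded with a warning."""
    usable = [p for p in points if p.pins > 0 and p.computation > 0]
    if len(usable) < len(list(points)):
        warnings.warn(f"excluded {len(list(points)) - len(usable)} Rent points "
                      "with zero pins or computation")
    if len(usable) < 2:
        raise ValueError("need >=2 points with positive pins and computation")
    x = np.log([p.computation for p in usable])
    y = np.log([p.pins for p in usable])
    res = sps.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    b = float(res.slope)
    return RentFit(a=float(np.exp(res.intercept)), b=b,
                   r_squared=float(res.rvalue ** 2), residuals=resid,
                   b_in_theory_range=0.0 <= b <= 1.0)


def classify_rent(b: float) -> str:
    """Place an exponent relative to the packing range [0.5, 0.7]
    (inclusive): ``below-packing``, ``packing-range`` or
    ``above-packing``."""
    lo, hi = PACKING_RANGE
    if b < lo:
        return "below-packing"
    if b > hi:
        return "above-packing"
    return "packing-range"
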