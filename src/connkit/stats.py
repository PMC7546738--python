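"""Per-region network statistics, path-length curves, connection-strength
distribution fitting, and connection-completeness checks.

The statistic bundle per region: neuron count N, connection count L, mean
number of distinct partners ⟨k⟩, network diameter D (maximum over finite
shortest paths, directed), mean connection strength split by reciprocal /
non-reciprocal, the reciprocal-edge fraction fracR, and the mean hop
count over reachable ordered pairs.  Unreachable ordered pairs are
excluded from D and the mean distance, and their count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize

from .core import ConnectomeGraph, threshold_graph
from .synth import truncated_powerlaw_pmf

__all__ = [
    "CompartmentStats",
    "StrengthFit",
    "PathCurve",
    "compartment_summary",
    "path_length_curve",
    "fit_strength_distribution",
    "detection_probability",
    "completeness_delta",
    "mean_psds_per_tbar",
    "both_wrong_probability",
]


@dataclass
class CompartmentStats:
    region: str
    n_neurons: int
    n_connections: int
    k_avg: float
    diameter: int
    str_avg: float
    str_nonrecip: float
    str_recip: float
    frac_recip: float
    avg_dist: float
    n_unreachable_pairs: int


@dataclass
class StrengthFit:
    gamma: float
    kappa: float
    k_range: tuple
    log_likelihood: float
    se_gamma: float
    se_kappa: float
    n_used: int
    n_excluded: int


@dataclass
class PathCurve:
    threshold: int
    points: list  # [(n_interneurons, cumulative fraction of ordered pairs)]


def compartment_summary(g: ConnectomeGraph, region: str = "") -> CompartmentStats:
    """Compute the per-region statistic bundle for ``g``.

    An edge (a,b) is reciprocal iff (b,a) also exists; fracR is the
    fraction of edges that are reciprocal (a fully bidirectional graph
    scores 1.0).  Distances are directed hop counts; diameter and the
    average distance run over ordered pairs with a finite path only.
    """
    G = g.nx
    n = G.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    L = G.number_of_edges()

    partners = [len(set(G.predecessors(v)) | set(G.successors(v))) for v in G]
    k_avg = float(np.mean(partners))

    recip_w, nonrecip_w = [], []
    for u, v, d in G.edges(data=True):
        (recip_w if G.has_edge(v, u) else nonrecip_w).append(d["weight"])
    all_w = recip_w + nonrecip_w
    frac_recip = len(recip_w) / L if L else 0.0

    total, count, diameter = 0, 0, 0
    for v in G:
        dist = nx.single_source_shortest_path_length(G, v)
        for target, h in dist.items():
            if target == v:
                continue
            total += h
            count += 1
            if h > diameter:
                diameter = h
    avg_dist = total / count if count else float("nan")
    unreachable = n * (n - 1) - count

    return CompartmentStats(
        region=region, n_neurons=n, n_connections=L, k_avg=k_avg,
        diameter=diameter,
        str_avg=float(np.mean(all_w)) if all_w else float("nan"),
        str_nonrecip=float(np.mean(nonrecip_w)) if nonrecip_w else float("nan"),
        str_recip=float(np.mean(recip_w)) if recip_w else float("nan"),
        frac_recip=frac_recip, avg_dist=avg_dist,
        n_unreachable_pairs=unreachable,
    )


def path_length_curve(g: ConnectomeGraph, thresholds) -> list[PathCurve]:
    """Fraction of ordered neuron pairs connected versus the number of
    interneurons required, per synapse-count threshold.

    A pair whose shortest path is h hops needs h−1 interneurons.  The
    denominator is N(N−1) over all ordered pairs; pairs with no path are
    never counted as connected, so curves may saturate below 1.
    """
    curves = []
    n = g.n_neurons
    denom = n * (n - 1)
    for thr in thresholds:
        gt = threshold_graph(g, thr)
        hist: dict[int, int] = {}
        for v in gt.nx:
            for target, h in nx.single_source_shortest_path_length(gt.nx, v).items():
                if target != v:
                    hist[h - 1] = hist.get(h - 1, 0) + 1
        points = []
        cum = 0
        for k in range(max(hist) + 1 if hist else 0):
            cum += hist.get(k, 0)
            points.append((k, cum / denom if denom else 0.0))
        curves.append(PathCurve(threshold=int(thr), points=points))
    return curves


def _nll(params, counts, k):
    """Exact negative log-likelihood of the truncated power law with
    exponential cutoff, parameterized as (gamma, log kappa)."""
    gamma, log_kappa = params
    kappa = np.exp(log_kappa)
    logw = -gamma * np.log(k) - k / kappa
    m = logw.max()
    log_z = m + np.log(np.exp(logw - m).sum())
    n = counts.sum()
    return float(n * log_z + gamma * (counts * np.log(k)).sum()
                 + (counts * k).sum() / kappa)


def fit_strength_distribution(weights, k_min: int = 1, k_max: int = 100,
                              gamma0: float = 1.5,
                              kappa0: float = 30.0) -> StrengthFit:
    """Maximum-likelihood fit of P(k) ∝ k^(−gamma)·exp(−k/kappa) on
    {k_min..k_max} by direct numerical optimization of the exact discrete
    log-likelihood.  Weights outside the range are excluded and counted.

    Standard errors come from the observed-information matrix (numerical
    Hessian at the optimum), with the kappa error mapped back from the
    internal log-kappa parameterization.
    """
    w = np.asarray(weights, dtype=int)
    in_range = (w >= k_min) & (w <= k_max)
    used = w[in_range]
    if used.size == 0 or np.unique(used).size < 2:
        raise ValueError(
            "degenerate strength sample: need >=2 distinct weights in "
            f"[{k_min}, {k_max}], got {np.unique(used).size}")
    k = np.arange(k_min, k_max + 1, dtype=float)
    counts = np.bincount(used, minlength=k_max + 1)[k_min:k_max + 1].astype(float)

    res = optimize.minimize(
        _nll, x0=[gamma0, np.log(kappa0)], args=(counts, k),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 5000})
    gamma, log_kappa = res.x
    kappa = float(np.exp(log_kappa))

    # numerical Hessian of the NLL at the optimum
    h = 1e-4
    H = np.zeros((2, 2))
    x0 = res.x
    for i in range(2):
        for j in range(2):
            xpp = x0.copy(); xpp[i] += h; xpp[j] += h
            xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = (_nll(xpp, counts, k) - _nll(xpm, counts, k)
                       - _nll(xmp, counts, k) + _nll(xmm, counts, k)) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        se_gamma = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_kappa = float(np.sqrt(max(cov[1, 1], 0.0)) * kappa)  # delta method
    except np.linalg.LinAlgError:
        se_gamma = se_kappa = float("nan")

    return StrengthFit(
        gamma=float(gamma), kappa=kappa, k_range=(k_min, k_max),
        log_likelihood=-float(res.fun), se_gamma=se_gamma, se_kappa=se_kappa,
        n_used=int(used.size), n_excluded=int(w.size - used.size))


def detection_probability(n_synapses: int, trace_rate: float) -> float:
    """Probability that a connection of ``n_synapses`` parallel synapses
    appears in the reconstruction when each synapse is independently
    traced with probability ``trace_rate``: 1 − (1 − trace_rate)^n.

    A 10-synapse connection at a 50% trace rate is found with >99.9%
    probability — why sampled (incomplete) tracing still recovers the
    circuit of strong connections.
    """
    if not 0.0 <= trace_rate <= 1.0:
        raise ValueError("trace_rate must be in [0, 1]")
    if n_synapses < 1:
        raise ValueError("n_synapses must be >= 1")
    return 1.0 - (1.0 - trace_rate) ** n_synapses


def completeness_delta(g_before: ConnectomeGraph, g_after: ConnectomeGraph):
    """Per-pair weight comparison between two proofreading states.

    Returns ``(table, summary)``: a DataFrame with one row per ordered
    pair present in either graph (pre_id, post_id, w_before, w_after) and
    counts of increased / decreased / unchanged pairs and of new strong
    pairs (absent before, >=10 synapses after).  On a healthy
    proofreading trajectory almost all changed pairs increase and no new
    strong connections appear.
    """
    before = {(u, v): w for u, v, w, _ in g_before.edges()}
    after = {(u, v): w for u, v, w, _ in g_after.edges()}
    pairs = sorted(set(before) | set(after))
    rows = [{"pre_id": u, "post_id": v,
             "w_before": before.get((u, v), 0),
             "w_after": after.get((u, v), 0)} for u, v in pairs]
    table = pd.DataFrame(rows, columns=["pre_id", "post_id", "w_before", "w_after"])
    delta = table["w_after"] - table["w_before"]
    summary = {
        "increased": int((delta > 0).sum()),
        "decreased": int((delta < 0).sum()),
        "unchanged": int((delta == 0).sum()),
        "new_strong": int(((table["w_before"] == 0) & (table["w_after"] >= 10)).sum()),
    }
    return table, summary


def mean_psds_per_tbar(n_psds: float, n_tbars: float) -> float:
    """Average number of postsynaptic densities per presynaptic T-bar
    (fly synapses are polyadic; ~6.7 in dense central-brain data)."""
    if n_tbars <= 0:
        raise ValueError("n_tbars must be > 0")
    return n_psds / n_tbars


def both_wrong_probability(precision: float) -> float:
    """Probability that both synapses of a two-synapse connection are
    false positives, assuming independent errors: (1 − precision)²."""
    if not 0.0 <= precision <= 1.0:
        raise ValueError("precision must be in [0, 1]")
    return (1.0 - precision) ** 2
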