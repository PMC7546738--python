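"""Small- and large-motif analysis.

Large motifs are graph structures involving every cell of an abundant
type (N ≥ 20).  The tightest is a clique: every cell of a type
bidirectionally connected to (nearly) every other cell of the same type.
Under random wiring with per-ordered-pair probability p, a complete
clique over m cells has probability p^(m(m−1)) — about 10^−432 for 25
cells at p = 0.19 — so observed cliques are overwhelmingly non-random.
One-to-many ("overseer") motifs connect a sparse type (1–2 cells) to at
least 90% of an abundant type, uni- or bidirectionally; the classic
example is a gain-control neuron reading out and inhibiting a large
population.  The small-motif analysis here is the reciprocity census
against a degree-preserving rewiring null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ConnectomeGraph, restrict_to_roi

__all__ = [
    "CliqueReport",
    "OverseerReport",
    "find_cliques",
    "find_one_to_many",
    "clique_log_null",
    "count_ordered_pairs",
    "reciprocity_null",
]


@dataclass
class CliqueReport:
    type_name: str
    cells_included: int      # cells meeting the per-cell partner criterion
    cells_total: int
    edges_present: int
    edges_possible: int      # m(m-1) ordered pairs over all cells of the type
    avg_strength: float      # total_synapses / edges_present
    total_synapses: int
    region: str = ""


@dataclass
class OverseerReport:
    overseer_ids: tuple
    overseer_type: str
    target_type: str
    direction: str
    covered_fraction: float
    mean_synapses_per_target: float


def count_ordered_pairs(n: int) -> int:
    """Number of ordered pairs among n cells: n(n−1)."""
    return n * (n - 1)


def clique_log_null(n_cells: int, p_conn: float) -> float:
    """log10 probability that all n(n−1) ordered connections among
    ``n_cells`` are present under an independent-edge null with
    per-ordered-pair probability ``p_conn``."""
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    if not 0.0 < p_conn <= 1.0:
        raise ValueError("p_conn must be in (0, 1] (0 gives -infinity)")
    return count_ordered_pairs(n_cells) * math.log10(p_conn)


def _bidirectional(G, u, v, min_weight):
    return (G.has_edge(u, v) and G.edges[u, v]["weight"] >= min_weight
            and G.has_edge(v, u) and G.edges[v, u]["weight"] >= min_weight)


def find_cliques(g: ConnectomeGraph, min_cells: int = 20,
                 member_frac: float = 0.9, partner_frac: float = 0.9,
                 region: str | None = None,
                 min_weight: int = 1) -> list[CliqueReport]:
    """Detect cell types forming cliques or near-cliques.

    A type with at least ``min_cells`` instances is reported when at
    least ``member_frac`` of its cells have bidirectional connections
    (weight ≥ ``min_weight`` each way) to at least ``partner_frac`` of
    the *other* cells of the type.  Coverage and strength are computed
    over all ordered pairs among all cells of the type.  With ``region``
    given, only the per-region synapse counts in that region count
    (the per-compartment clique case).
    """
    if not any(d["type_name"] for _, d in g.nx.nodes(data=True)):
        raise ValueError("graph carries no cell-type labels")
    if region is not None:
        g = restrict_to_roi(g, region)
    G = g.nx
    reports = []
    for type_name, m in sorted(g.type_census().items()):
        if m < min_cells:
            continue
        cells = g.bodies_of_type(type_name)
        m = len(cells)
        qualifying = 0
        for c in cells:
            n_bidir = sum(1 for o in cells
                          if o != c and _bidirectional(G, c, o, min_weight))
            if n_bidir >= partner_frac * (m - 1):
                qualifying += 1
        if qualifying < member_frac * m:
            continue
        edges_present = total = 0
        for u in cells:
            for v in cells:
                if u != v and G.has_edge(u, v):
                    w = G.edges[u, v]["weight"]
                    if w >= min_weight:
                        edges_present += 1
                        total += w
        reports.append(CliqueReport(
            type_name=type_name, cells_included=qualifying, cells_total=m,
            edges_present=edges_present,
            edges_possible=count_ordered_pairs(m),
            avg_strength=total / edges_present if edges_present else 0.0,
            total_synapses=total, region=region or ""))
    return reports


def find_one_to_many(g: ConnectomeGraph, sparse_max: int = 2,
                     abundant_min: int = 20, coverage: float = 0.9,
                     direction: str = "both",
                     min_weight: int = 1) -> list[OverseerReport]:
    """Detect one-to-many (overseer) motifs.

    For every type with at most ``sparse_max`` instances and every type
    with at least ``abundant_min`` instances, report the pair when every
    sparse-type cell is connected, in the stated direction(s), to at
    least ``coverage`` of the abundant type's cells.  ``direction``:
    ``both`` (bidirectional), ``out`` (overseer→targets) or ``in``
    (targets→overseer).
    """
    if direction not in ("both", "in", "out"):
        raise ValueError(f"direction must be both|in|out, got {direction!r}")
    G = g.nx
    census = g.type_census()
    sparse_types = [t for t, n in census.items() if n <= sparse_max]
    abundant_types = [t for t, n in census.items() if n >= abundant_min]

    def connected(o, t):
        if direction == "both":
            return _bidirectional(G, o, t, min_weight)
        u, v = (o, t) if direction == "out" else (t, o)
        return G.has_edge(u, v) and G.edges[u, v]["weight"] >= min_weight

    reports = []
    for st in sorted(sparse_types):
        overseers = g.bodies_of_type(st)
        for at in sorted(abundant_types):
            if at == st:
                continue
            targets = g.bodies_of_type(at)
            fracs, syn_per_target = [], []
            for o in overseers:
                hit = [t for t in targets if connected(o, t)]
                fracs.append(len(hit) / len(targets))
                syn = 0
                for t in hit:
                    if G.has_edge(o, t):
                        syn += G.edges[o, t]["weight"]
                    if G.has_edge(t, o):
                        syn += G.edges[t, o]["weight"]
                syn_per_target.append(syn / len(targets))
            if fracs and all(f >= coverage for f in fracs):
                reports.append(OverseerReport(
                    overseer_ids=tuple(overseers), overseer_type=st,
                    target_type=at, direction=direction,
                    covered_fraction=float(np.mean(fracs)),
                    mean_synapses_per_target=float(np.mean(syn_per_target))))
    return reports


def _rewire(G_edges, n_nodes_edges, rng, n_swaps):
    """Degree-preserving double-edge swaps on an edge set (as a set of
    ordered pairs); returns the rewired edge set."""
    edges = list(G_edges)
    edge_set = set(edges)
    m = len(edges)
    done = 0
    attempts = 0
    max_attempts = 40 * n_swaps + 100
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # swap targets: (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.remove((a, b)); edge_set.remove((c, d))
        edge_set.add((a, d)); edge_set.add((c, b))
        edges[i] = (a, d); edges[j] = (c, b)
        done += 1
    return edge_set


def _frac_recip(edge_set) -> float:
    if not edge_set:
        return 0.0
    return sum(1 for (u, v) in edge_set if (v, u) in edge_set) / len(edge_set)


def reciprocity_null(g: ConnectomeGraph, n_permutations: int, seed: int):
    """Observed reciprocal-edge fraction against a degree-preserving
    rewiring null.

    The null preserves each neuron's in- and out-degree sequence (double
    edge swaps, 10 swaps per edge per sample).  Returns a dict with the
    observed fraction, null mean and SD, and a z-score (defined as 0 when
    the null has zero variance and the observation equals its mean, e.g.
    a complete digraph where no rewiring is possible).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    edges = [(u, v) for u, v, _, _ in g.edges()]
    observed = _frac_recip(set(edges))
    n_swaps = 10 * len(edges)
    null = np.array([
        _frac_recip(_rewire(edges, g.n_neurons, rng, n_swaps))
        for _ in range(n_permutations)])
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    if sd == 0.0:
        z = 0.0 if np.isclose(observed, mean) else float("inf") * np.sign(observed - mean)
    else:
        z = (observed - mean) / sd
    return {"observed_frac_recip": observed, "null_mean": mean,
            "null_sd": sd, "z": float(z), "n_permutations": int(n_permutations)}
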