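"""Seeded synthetic-connectome generators.

These generators emulate the statistical structure measured in dense fly
connectomes so every downstream analysis is testable without the real
dataset: dense directed wiring (per-ordered-pair connection probability
around 0.19 in a central-complex-like region), synapse-count edge weights
from a discrete power law with exponential cutoff (exponent 1.67, cutoff
42), excess reciprocity, planted cliques and one-to-many "overseer"
motifs, block-model cell types with distinct connectivity fingerprints,
and branched region-labelled skeletons.

All generators are pure functions of their configuration and seed.
Sub-streams are derived from the one global seed by fixed offsets, so
adding a generator never perturbs existing outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConnectomeGraph, Skeleton, write_connectome, write_swc

__all__ = [
    "GeneratorConfig",
    "sample_strengths",
    "truncated_powerlaw_pmf",
    "generate_connectome",
    "plant_clique",
    "plant_overseer",
    "generate_skeleton",
    "generate_block_connectome",
    "separated_profiles",
    "write_simulation",
]

# fixed sub-stream offsets (see module docstring)
_STREAM_EDGES = 0
_STREAM_WEIGHTS = 1
_STREAM_ROIS = 2
_STREAM_CLIQUE = 3
_STREAM_OVERSEER = 4
_STREAM_SKELETON = 5
_STREAM_BLOCK = 6


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(offset)]))


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic connectome.

    Defaults emulate an ellipsoid-body-like region: per-ordered-pair
    connection probability 0.19; weights from a discrete power law with
    exponent 1.67 and exponential cutoff 42 on support 1..100; the
    reciprocity boost raises the conditional probability of the return
    edge so the reciprocal-edge fraction approaches the ~0.7 measured in
    that region while the marginal edge density stays at ``p_conn``.
    """

    n_neurons: int = 300
    type_plan: list = field(default_factory=list)  # [(type_name, n_cells), ...]
    regions: list = field(default_factory=lambda: [("EB", 3.0), ("PB", 2.0), ("GA", 1.0)])
    p_conn: float = 0.19
    strength_params: tuple = (1.67, 42.0, 100)  # (gamma, kappa, k_max)
    reciprocity_boost: float = 3.8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_conn <= 1.0:
            raise ValueError("p_conn must be in [0, 1]")
        if self.reciprocity_boost < 1.0:
            raise ValueError("reciprocity_boost must be >= 1")
        gamma, kappa, k_max = self.strength_params
        if int(k_max) < 1:
            raise ValueError("k_max must be >= 1")
        if sum(n for _, n in self.type_plan) > self.n_neurons:
            raise ValueError("type_plan assigns more cells than n_neurons")


def truncated_powerlaw_pmf(gamma: float, kappa: float, k_max: int) -> np.ndarray:
    """Normalized pmf P(k) ∝ k^(-gamma) · exp(-k/kappa) on k = 1..k_max."""
    k_max = int(k_max)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    k = np.arange(1, k_max + 1, dtype=float)
    logp = -gamma * np.log(k) - k / kappa
    logp -= logp.max()
    p = np.exp(logp)
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("non-normalizable strength parameters")
    return p / total


def sample_strengths(gamma: float, kappa: float, k_max: int, n: int,
                     seed) -> np.ndarray:
    """Draw ``n`` i.i.d. synapse counts from the truncated power law with
    exponential cutoff, by exact inverse-CDF on the normalized table.

    ``seed`` may be an integer or an already-constructed Generator.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pmf = truncated_powerlaw_pmf(gamma, kappa, k_max)
    if n == 0:
        return np.empty(0, dtype=int)
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    u = rng.random(int(n))
    return np.searchsorted(cdf, u, side="right") + 1


def _assign_types(g: ConnectomeGraph, ids, type_plan):
    pos = 0
    for type_name, n_cells in type_plan:
        for bid in ids[pos:pos + n_cells]:
            g.nx.nodes[bid]["type_name"] = type_name
        pos += n_cells


def generate_connectome(config: GeneratorConfig) -> ConnectomeGraph:
    """Generate a directed connectome per ``config``.

    Each ordered pair is connected with probability ``p_conn``; given the
    forward edge, the return edge's probability is boosted by
    ``reciprocity_boost`` (and compensated downward when the forward edge
    is absent, so the marginal density remains exactly ``p_conn`` whenever
    the compensation is feasible; probabilities are clipped to [0, 1]).
    Weights are drawn from the truncated power law and split across
    regions by a per-synapse categorical draw proportional to region
    volumes; those splits also populate each neuron's per-region
    synapse counts.
    """
    n = config.n_neurons
    p = config.p_conn
    gamma, kappa, k_max = config.strength_params
    rng_e = _rng(config.seed, _STREAM_EDGES)
    rng_w = _rng(config.seed, _STREAM_WEIGHTS)
    rng_r = _rng(config.seed, _STREAM_ROIS)

    p_fwd = min(1.0, config.reciprocity_boost * p)
    # compensate so that P(back edge) = p marginally
    p_back_given_no_fwd = 0.0 if p >= 1 else max(0.0, p * (1 - p_fwd) / (1 - p))

    g = ConnectomeGraph(r for r, _ in config.regions)
    ids = list(range(1, n + 1))
    for bid in ids:
        g.add_neuron(bid)
    _assign_types(g, ids, config.type_plan)

    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            fwd = rng_e.random() < p
            p_back = p_fwd if fwd else p_back_given_no_fwd
            back = rng_e.random() < p_back
            if fwd:
                edges.append((ids[i], ids[j]))
            if back:
                edges.append((ids[j], ids[i]))

    weights = sample_strengths(gamma, kappa, k_max, len(edges), rng_w)
    roi_names = [r for r, _ in config.regions]
    vols = np.array([v for _, v in config.regions], dtype=float)
    probs = vols / vols.sum() if len(vols) else None

    for (u, v), w in zip(edges, weights):
        rw = None
        if probs is not None:
            counts = rng_r.multinomial(int(w), probs)
            rw = {roi: int(c) for roi, c in zip(roi_names, counts) if c}
        g.add_edge(u, v, int(w), rw)

    _refresh_roi_counts(g)
    return g


def _refresh_roi_counts(g: ConnectomeGraph):
    """Derive per-neuron region synapse counts from edge roi_weights."""
    counts = {n: {} for n in g.nx.nodes}
    for u, v, _, rw in g.edges():
        for roi, w in rw.items():
            pre = counts[u].setdefault(roi, [0, 0])
            pre[0] += w
            post = counts[v].setdefault(roi, [0, 0])
            post[1] += w
    for n in g.nx.nodes:
        g.nx.nodes[n]["roi_counts"] = {r: (a, b) for r, (a, b) in counts[n].items()}


def plant_clique(g: ConnectomeGraph, type_name: str, n_cells: int,
                 mean_strength: float, seed: int,
                 roi: str | None = None) -> ConnectomeGraph:
    """Plant a complete bidirectional clique.

    The first ``n_cells`` untyped neurons are relabelled ``type_name`` and
    every ordered pair among them is connected with weight
    1 + Poisson(mean_strength - 1), overwriting any existing edge (so the
    weight floor of 1 is preserved while the mean targets
    ``mean_strength``).
    """
    if mean_strength < 1:
        raise ValueError("mean_strength must be >= 1")
    rng = _rng(seed, _STREAM_CLIQUE)
    out = g.copy()
    untyped = [n for n in out.nx.nodes if not out.nx.nodes[n]["type_name"]]
    if len(untyped) < n_cells:
        raise ValueError(f"need {n_cells} untyped neurons, have {len(untyped)}")
    members = untyped[:n_cells]
    for bid in members:
        out.nx.nodes[bid]["type_name"] = type_name
    for u in members:
        for v in members:
            if u == v:
                continue
            w = 1 + int(rng.poisson(mean_strength - 1))
            if out.nx.has_edge(u, v):
                out.nx.remove_edge(u, v)
            out.add_edge(u, v, w, {roi: w} if roi else None)
    _refresh_roi_counts(out)
    return out


def plant_overseer(g: ConnectomeGraph, target_type: str, n_overseers: int,
                   coverage_frac: float, direction: str, seed: int,
                   overseer_type: str = "overseer",
                   mean_strength: float = 5.0) -> ConnectomeGraph:
    """Plant a one-to-many (overseer) motif.

    ``n_overseers`` new neurons of type ``overseer_type`` are added; each
    is connected to ceil(coverage_frac · N_target) randomly chosen cells
    of ``target_type``, in the stated direction(s) (``both``, ``in`` =
    target→overseer, or ``out`` = overseer→target).
    """
    if direction not in ("both", "in", "out"):
        raise ValueError(f"direction must be both|in|out, got {direction!r}")
    if not 0.0 <= coverage_frac <= 1.0:
        raise ValueError("coverage_frac must be in [0, 1]")
    rng = _rng(seed, _STREAM_OVERSEER)
    out = g.copy()
    targets = out.bodies_of_type(target_type)
    if not targets:
        raise ValueError(f"no cells of type {target_type!r}")
    n_cover = math.ceil(coverage_frac * len(targets))
    next_id = max(out.body_ids()) + 1
    for k in range(n_overseers):
        oid = next_id + k
        out.add_neuron(oid, type_name=overseer_type)
        chosen = rng.choice(targets, size=n_cover, replace=False)
        for t in chosen:
            t = int(t)
            if direction in ("both", "out"):
                w = 1 + int(rng.poisson(mean_strength - 1))
                if out.nx.has_edge(oid, t):
                    out.nx.remove_edge(oid, t)
                out.add_edge(oid, t, w)
            if direction in ("both", "in"):
                w = 1 + int(rng.poisson(mean_strength - 1))
                if out.nx.has_edge(t, oid):
                    out.nx.remove_edge(t, oid)
                out.add_edge(t, oid, w)
    return out


# ---------------------------------------------------------------------
# skeletons
# ---------------------------------------------------------------------

def generate_skeleton(n_regions: int, nodes_per_region: int,
                      neurite_length_um: float, radius_um_range: tuple,
                      seed: int, region_names=None) -> Skeleton:
    """Generate a branched, region-labelled skeleton.

    Per region: a random binary arbor of ``nodes_per_region`` labelled
    nodes with short (~2 μm) segments and radii drawn from
    ``radius_um_range``.  Consecutive regions are joined by a long thin
    unbranched neurite of total length ``neurite_length_um`` (10
    segments, radius at the low end of the range) — the geometry of a
    central-complex projection neuron arborizing in several compartments
    connected by thin processes.
    """
    if n_regions < 1 or nodes_per_region < 1:
        raise ValueError("n_regions and nodes_per_region must be >= 1")
    r_lo, r_hi = radius_um_range
    if r_lo <= 0 or r_hi < r_lo:
        raise ValueError("invalid radius range")
    rng = _rng(seed, _STREAM_SKELETON)
    if region_names is None:
        region_names = [f"R{i}" for i in range(1, n_regions + 1)]

    rows = []
    next_id = 1

    def add_node(parent, x, y, z, radius, label):
        nonlocal next_id
        rows.append({"node_id": next_id, "struct_type": 0, "x": x, "y": y,
                     "z": z, "radius": radius, "parent_id": parent,
                     "label": label})
        next_id += 1
        return next_id - 1

    anchor = None  # node the next region attaches to
    origin = np.zeros(3)
    for ri, label in enumerate(region_names[:n_regions]):
        if anchor is None:
            root = add_node(-1, *origin, rng.uniform(r_lo, r_hi), label)
        else:
            # long thin unbranched neurite to the next region; neurite
            # nodes are labelled by the nearer flanking region so the
            # inter-region boundary is crossed by exactly one edge
            n_seg = 10
            step = neurite_length_um / n_seg
            direction = np.array([1.0, 0.0, 0.0])
            prev_label = region_names[ri - 1]
            prev = anchor
            pos = origin.copy()
            for s in range(n_seg):
                pos = pos + direction * step
                seg_label = prev_label if s < n_seg // 2 else label
                prev = add_node(prev, *pos, r_lo, seg_label)
            origin = pos
            root = prev
        # random binary arbor around origin
        arbor = [root]
        child_count = {root: 0}
        n_more = nodes_per_region - 1
        for _ in range(n_more):
            open_nodes = [a for a in arbor if child_count[a] < 2]
            parent = int(rng.choice(open_nodes))
            px = rows[parent - 1]
            pos = np.array([px["x"], px["y"], px["z"]]) + rng.normal(0, 1.2, 3)
            nid = add_node(parent, *pos, rng.uniform(r_lo, r_hi), label)
            child_count[parent] += 1
            child_count[nid] = 0
            arbor.append(nid)
        anchor = root

    return Skeleton(pd.DataFrame(rows))


# ---------------------------------------------------------------------
# block-model cell types
# ---------------------------------------------------------------------

def separated_profiles(n_types: int, p_hi: float = 0.6,
                       p_lo: float = 0.02) -> np.ndarray:
    """Type→type connection-probability matrix in which every true type
    has a distinct input and output fingerprint: type t projects densely
    to type (t+1) mod n and sparsely elsewhere."""
    P = np.full((n_types, n_types), p_lo)
    for t in range(n_types):
        P[t, (t + 1) % n_types] = p_hi
    return P


def generate_block_connectome(prob_matrix, cells_per_type: int, seed: int,
                              strength_params=(1.67, 42.0, 100),
                              type_names=None, background_max_weight: int = 2):
    """Stochastic block model over cell types.

    ``prob_matrix[s, t]`` is the probability that a cell of type s sends
    an edge to a cell of type t (rows are out-profiles, columns
    in-profiles).  Returns ``(graph, true_labels)`` where ``true_labels``
    maps body_id → true type index.

    Connection probability and strength are positively correlated across
    type pairs, as in real connectomes where type-defining connections
    are the strong, reproducible ones: edges of high-probability blocks
    (P[s,t] ≥ half the matrix maximum) draw weights from the full
    truncated power law, while sporadic background edges are weak
    (uniform on 1..``background_max_weight``).  Set
    ``background_max_weight=0`` to disable and draw all weights from the
    same distribution.
    """
    P = np.asarray(prob_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("prob_matrix must be square")
    if ((P < 0) | (P > 1)).any():
        raise ValueError("probabilities must be in [0, 1]")
    n_types = P.shape[0]
    if type_names is None:
        type_names = [f"T{t}" for t in range(n_types)]
    rng = _rng(seed, _STREAM_BLOCK)
    gamma, kappa, k_max = strength_params

    g = ConnectomeGraph()
    labels = {}
    bid = 1
    for t in range(n_types):
        for _ in range(cells_per_type):
            g.add_neuron(bid, type_name=type_names[t])
            labels[bid] = t
            bid += 1
    ids = list(labels)
    edges = []
    for u in ids:
        for v in ids:
            if u == v:
                continue
            if rng.random() < P[labels[u], labels[v]]:
                edges.append((u, v))
    weights = sample_strengths(gamma, kappa, k_max, len(edges), rng)
    signal_cut = 0.5 * P.max()
    for (u, v), w in zip(edges, weights):
        if background_max_weight and P[labels[u], labels[v]] < signal_cut:
            w = int(rng.integers(1, background_max_weight + 1))
        g.add_edge(u, v, int(w))
    return g, labels


# ---------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------

def write_simulation(out_dir, config: GeneratorConfig,
                     clique=None, overseer=None, skeleton=None) -> dict:
    """Generate a connectome (optionally with planted motifs and a
    skeleton) and write the standard CSV/SWC fixture set plus truth
    files (``true_types.csv``, ``planted_motifs.json``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = generate_connectome(config)
    planted = {}
    if clique is not None:
        g = plant_clique(g, **clique, seed=config.seed)
        planted["clique"] = dict(clique)
    if overseer is not None:
        g = plant_overseer(g, **overseer, seed=config.seed)
        planted["overseer"] = dict(overseer)
    paths = write_connectome(g, out_dir)
    truth = g.neuron_table().rename(columns={"type": "true_type"})
    truth[["body_id", "true_type"]].to_csv(out_dir / "true_types.csv", index=False)
    (out_dir / "planted_motifs.json").write_text(json.dumps(planted, indent=1))
    if skeleton is not None:
        skel = generate_skeleton(**skeleton, seed=config.seed)
        write_swc(skel, out_dir / "skeleton.swc", out_dir / "labels.tsv")
    return paths
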