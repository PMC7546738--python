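"""Connectome data model and flat-file I/O.

The central object is :class:`ConnectomeGraph`: a directed graph over
neurons in which each ordered pair of neurons carries at most one edge,
weighted by the number of parallel synapses between them (the field's
standard proxy for connection strength).  Edge weights may optionally be
broken down by brain region (neuropil), and each neuron may carry
per-region pre-/post-synapse counts.  Autapses (self-connections) are
rejected: in dense fly reconstructions putative autapses fall below the
false-positive rate of automated synapse detection and are excluded from
connectivity data.

Skeletons are rooted trees of 3-D points with radii (SWC format), with
region labels carried in a two-column sidecar table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ConnectomeGraph",
    "Skeleton",
    "classify_strength",
    "load_connectome",
    "write_connectome",
    "read_swc",
    "write_swc",
    "threshold_graph",
    "restrict_to_roi",
    "to_sparse_adjacency",
]

SWC_COLUMNS = ["node_id", "struct_type", "x", "y", "z", "radius", "parent_id"]


class ConnectomeGraph:
    """Directed weighted graph over neurons.

    Parameters
    ----------
    regions : iterable of str, optional
        Region-name vocabulary.  Grown automatically as edges or neurons
        carrying region annotations are added.
    """

    def __init__(self, regions=()):
        self._g = nx.DiGraph()
        self.regions: set[str] = set(regions)

    # -- construction -------------------------------------------------
    def add_neuron(self, body_id, type_name="", instance="", roi_counts=None):
        body_id = int(body_id)
        if body_id <= 0:
            raise ValueError(f"body_id must be positive, got {body_id}")
        roi_counts = dict(roi_counts or {})
        for roi, (pre, post) in roi_counts.items():
            if pre < 0 or post < 0:
                raise ValueError(f"negative synapse count for {body_id} in {roi}")
            self.regions.add(roi)
        self._g.add_node(
            body_id, type_name=type_name or "", instance=instance or "",
            roi_counts=roi_counts,
        )

    def add_edge(self, pre_id, post_id, weight, roi_weights=None):
        pre_id, post_id = int(pre_id), int(post_id)
        if pre_id == post_id:
            raise ValueError(f"autapse {pre_id}->{post_id} not allowed")
        for bid in (pre_id, post_id):
            if bid not in self._g:
                raise KeyError(f"edge endpoint {bid} not in neuron table")
        weight = int(weight)
        if weight < 1:
            raise ValueError(f"edge weight must be >= 1, got {weight}")
        if self._g.has_edge(pre_id, post_id):
            raise ValueError(f"duplicate edge ({pre_id}, {post_id})")
        roi_weights = {r: int(w) for r, w in (roi_weights or {}).items() if w}
        if roi_weights:
            if any(w < 0 for w in roi_weights.values()):
                raise ValueError("negative roi weight")
            if sum(roi_weights.values()) != weight:
                raise ValueError(
                    f"roi_weights of ({pre_id},{post_id}) sum to "
                    f"{sum(roi_weights.values())}, expected {weight}"
                )
            self.regions.update(roi_weights)
        self._g.add_edge(pre_id, post_id, weight=weight, roi_weights=roi_weights)

    # -- inspection ---------------------------------------------------
    @property
    def nx(self) -> nx.DiGraph:
        """The underlying networkx DiGraph (treat as read-only)."""
        return self._g

    @property
    def n_neurons(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def body_ids(self):
        return list(self._g.nodes)

    def neuron(self, body_id) -> dict:
        return self._g.nodes[body_id]

    def type_of(self, body_id) -> str:
        return self._g.nodes[body_id]["type_name"]

    def bodies_of_type(self, type_name) -> list[int]:
        return [n for n, d in self._g.nodes(data=True) if d["type_name"] == type_name]

    def type_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for _, d in self._g.nodes(data=True):
            t = d["type_name"]
            if t:
                census[t] = census.get(t, 0) + 1
        return census

    def weight(self, pre_id, post_id) -> int:
        return self._g.edges[pre_id, post_id]["weight"]

    def edge_weights(self) -> np.ndarray:
        return np.array([d["weight"] for _, _, d in self._g.edges(data=True)], dtype=int)

    def edges(self):
        """Iterate (pre_id, post_id, weight, roi_weights)."""
        for u, v, d in self._g.edges(data=True):
            yield u, v, d["weight"], d["roi_weights"]

    def copy(self) -> "ConnectomeGraph":
        out = ConnectomeGraph(self.regions)
        out._g = self._g.copy()
        return out

    def neuron_table(self) -> pd.DataFrame:
        rows = [
            {"body_id": n, "type": d["type_name"], "instance": d["instance"]}
            for n, d in self._g.nodes(data=True)
        ]
        return pd.DataFrame(rows, columns=["body_id", "type", "instance"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"pre_id": u, "post_id": v, "weight": d["weight"]}
            for u, v, d in self._g.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["pre_id", "post_id", "weight"])


def classify_strength(weight: int) -> str:
    """Classify a synapse count as ``weak`` (1-2), ``medium`` (3-9) or
    ``strong`` (>=10).

    A reported strong connection certainly exists and is strong; a weak
    one may not survive further proofreading.
    """
    weight = int(weight)
    if weight < 1:
        raise ValueError(f"connection weight must be >= 1, got {weight}")
    if weight <= 2:
        return "weak"
    if weight <= 9:
        return "medium"
    return "strong"


# ---------------------------------------------------------------------
# graph file I/O
# ---------------------------------------------------------------------

def load_connectome(nodes_path, edges_path, roi_counts_path=None,
                    edge_roi_path=None) -> ConnectomeGraph:
    """Load a connectome from delimited text tables.

    ``nodes.csv``: body_id,type,instance[,cell_body_fiber];
    ``edges.csv``: pre_id,post_id,weight;
    optional ``roi_counts.csv``: body_id,roi,pre,post and
    ``edge_roi.csv``: pre_id,post_id,roi,weight.

    Duplicate (pre,post) edge rows and edges referencing unknown body ids
    are hard errors.
    """
    nodes = pd.read_csv(nodes_path, dtype={"type": str, "instance": str},
                        keep_default_na=False)
    edges = pd.read_csv(edges_path)
    if nodes["body_id"].duplicated().any():
        dup = nodes.loc[nodes["body_id"].duplicated(), "body_id"].iloc[0]
        raise ValueError(f"duplicate body_id {dup} in neuron table")
    if len(edges) and edges.duplicated(subset=["pre_id", "post_id"]).any():
        d = edges.loc[edges.duplicated(subset=["pre_id", "post_id"])].iloc[0]
        raise ValueError(f"duplicate edge row ({d.pre_id}, {d.post_id})")

    roi_counts: dict[int, dict] = {}
    if roi_counts_path is not None:
        rc = pd.read_csv(roi_counts_path)
        for row in rc.itertuples():
            roi_counts.setdefault(int(row.body_id), {})[str(row.roi)] = (
                int(row.pre), int(row.post))

    g = ConnectomeGraph()
    for row in nodes.itertuples():
        g.add_neuron(row.body_id, type_name=getattr(row, "type", ""),
                     instance=getattr(row, "instance", ""),
                     roi_counts=roi_counts.get(int(row.body_id)))

    edge_roi: dict[tuple, dict] = {}
    if edge_roi_path is not None:
        er = pd.read_csv(edge_roi_path)
        for row in er.itertuples():
            key = (int(row.pre_id), int(row.post_id))
            edge_roi.setdefault(key, {})[str(row.roi)] = int(row.weight)

    for row in edges.itertuples():
        key = (int(row.pre_id), int(row.post_id))
        g.add_edge(*key, weight=row.weight, roi_weights=edge_roi.get(key))
    return g


def write_connectome(g: ConnectomeGraph, out_dir) -> dict[str, Path]:
    """Write the standard nodes/edges/roi CSVs; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    nodes = g.neuron_table()
    nodes["cell_body_fiber"] = ""
    paths["nodes"] = out_dir / "nodes.csv"
    nodes.to_csv(paths["nodes"], index=False)

    paths["edges"] = out_dir / "edges.csv"
    g.edge_table().to_csv(paths["edges"], index=False)

    rc_rows = []
    for n, d in g.nx.nodes(data=True):
        for roi, (pre, post) in sorted(d["roi_counts"].items()):
            rc_rows.append({"body_id": n, "roi": roi, "pre": pre, "post": post})
    paths["roi_counts"] = out_dir / "roi_counts.csv"
    pd.DataFrame(rc_rows, columns=["body_id", "roi", "pre", "post"]).to_csv(
        paths["roi_counts"], index=False)

    er_rows = []
    for u, v, _, rw in g.edges():
        for roi, w in sorted(rw.items()):
            er_rows.append({"pre_id": u, "post_id": v, "roi": roi, "weight": w})
    paths["edge_roi"] = out_dir / "edge_roi.csv"
    pd.DataFrame(er_rows, columns=["pre_id", "post_id", "roi", "weight"]).to_csv(
        paths["edge_roi"], index=False)
    return paths


# ---------------------------------------------------------------------
# graph transforms
# ---------------------------------------------------------------------

def threshold_graph(g: ConnectomeGraph, min_weight: int) -> ConnectomeGraph:
    """Drop edges with weight below ``min_weight``; neurons are retained
    even if they become isolated."""
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    out = g.copy()
    drop = [(u, v) for u, v, d in out.nx.edges(data=True)
            if d["weight"] < min_weight]
    out.nx.remove_edges_from(drop)
    return out


def restrict_to_roi(g: ConnectomeGraph, roi: str) -> ConnectomeGraph:
    """Restrict the graph to one brain region.

    Edge weights are replaced by the per-region synapse count for ``roi``
    (edges with no synapses there are dropped); the node set becomes the
    neurons with at least one pre- or post-synapse in the region.
    """
    if roi not in g.regions:
        raise KeyError(f"unknown region {roi!r}")
    out = ConnectomeGraph(g.regions)
    for n, d in g.nx.nodes(data=True):
        pre, post = d["roi_counts"].get(roi, (0, 0))
        if pre + post > 0:
            out.add_neuron(n, d["type_name"], d["instance"], d["roi_counts"])
    for u, v, _, rw in g.edges():
        w = rw.get(roi, 0)
        if w > 0:
            # endpoints with synapses only recorded at edge level still belong
            for bid in (u, v):
                if bid not in out.nx:
                    d = g.neuron(bid)
                    out.add_neuron(bid, d["type_name"], d["instance"], d["roi_counts"])
            out.add_edge(u, v, w, {roi: w})
    return out


def to_sparse_adjacency(g: ConnectomeGraph):
    """Coordinate-triplet adjacency plus an id-to-index map.

    Returns ``(triplets, id_map)`` DataFrames with columns
    (row, col, weight) and (body_id, index).
    """
    ids = sorted(g.body_ids())
    index = {b: i for i, b in enumerate(ids)}
    rows = [{"row": index[u], "col": index[v], "weight": w}
            for u, v, w, _ in g.edges()]
    triplets = pd.DataFrame(rows, columns=["row", "col", "weight"])
    id_map = pd.DataFrame({"body_id": ids, "index": range(len(ids))})
    return triplets, id_map


# ---------------------------------------------------------------------
# skeletons
# ---------------------------------------------------------------------

@dataclass
class Skeleton:
    """Rooted tree skeleton: one row per node.

    ``nodes`` columns: node_id, struct_type, x, y, z, radius, parent_id
    (parent_id = -1 at the root), plus a ``label`` column carrying the
    brain-region label (empty string when unlabelled).  Coordinates and
    radii are in micrometres.
    """

    nodes: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self):
        n = self.nodes
        ids = n["node_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate node ids in skeleton")
        if (n["radius"] <= 0).any():
            raise ValueError("skeleton radii must be > 0")
        roots = n[n["parent_id"] == -1]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        id_set = set(int(i) for i in ids)
        for pid in n.loc[n["parent_id"] != -1, "parent_id"]:
            if int(pid) not in id_set:
                raise ValueError(f"parent {pid} not in node table")
        # acyclic by construction if every non-root reaches the root
        parent = dict(zip(n["node_id"].astype(int), n["parent_id"].astype(int)))
        root = int(roots["node_id"].iloc[0])
        seen_ok = {root}
        for start in parent:
            path = []
            cur = start
            while cur not in seen_ok:
                path.append(cur)
                cur = parent[cur]
                if cur in path:
                    raise ValueError("cycle detected in skeleton parent links")
            seen_ok.update(path)

    @property
    def root(self) -> int:
        return int(self.nodes.loc[self.nodes["parent_id"] == -1, "node_id"].iloc[0])

    def edge_list(self) -> list[tuple[int, int]]:
        """(parent, child) pairs."""
        n = self.nodes
        mask = n["parent_id"] != -1
        return list(zip(n.loc[mask, "parent_id"].astype(int),
                        n.loc[mask, "node_id"].astype(int)))

    def coordinates(self) -> dict[int, np.ndarray]:
        return {int(r.node_id): np.array([r.x, r.y, r.z])
                for r in self.nodes.itertuples()}

    def radii(self) -> dict[int, float]:
        return dict(zip(self.nodes["node_id"].astype(int), self.nodes["radius"]))

    def labels(self) -> dict[int, str]:
        return dict(zip(self.nodes["node_id"].astype(int), self.nodes["label"]))

    def total_cable_length(self) -> float:
        xyz = self.coordinates()
        return float(sum(np.linalg.norm(xyz[u] - xyz[v])
                         for u, v in self.edge_list()))


def read_swc(path, labels_path=None, scale: float = 1.0) -> Skeleton:
    """Read a standard 7-column SWC file (order-independent: a node's
    parent may appear later in the file).  ``scale`` multiplies
    coordinates and radii (for files not in micrometres)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC line: {line!r}")
            rows.append(parts)
    nodes = pd.DataFrame(rows, columns=SWC_COLUMNS)
    nodes = nodes.astype({"node_id": int, "struct_type": int, "x": float,
                          "y": float, "z": float, "radius": float,
                          "parent_id": int})
    nodes[["x", "y", "z", "radius"]] *= scale
    nodes["label"] = ""
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", dtype={"roi": str},
                          keep_default_na=False)
        mapping = dict(zip(lab["node_id"].astype(int), lab["roi"]))
        nodes["label"] = nodes["node_id"].map(mapping).fillna("")
    return Skeleton(nodes.reset_index(drop=True))


def write_swc(skel: Skeleton, path, labels_path=None):
    """Write SWC (and optionally the labels.tsv sidecar)."""
    with open(path, "w") as fh:
        fh.write("# node_id struct_type x y z radius parent_id\n")
        for r in skel.nodes.itertuples():
            fh.write(f"{int(r.node_id)} {int(r.struct_type)} "
                     f"{r.x:.6f} {r.y:.6f} {r.z:.6f} {r.radius:.6f} "
                     f"{int(r.parent_id)}\n")
    if labels_path is not None:
        lab = skel.nodes.loc[skel.nodes["label"] != "", ["node_id", "label"]]
        lab = lab.rename(columns={"label": "roi"})
        lab.to_csv(labels_path, sep="\t", index=False)
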