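"""Connectivity-based cell-type clustering (CBLAST).

Each neuron is described by how it distributes its input and output
synapses across partner cell types: the feature vector concatenates the
fraction of input weight received from each type with the fraction of
output weight sent to each type.  Clustering these fingerprints groups
neurons of the same connectivity type; because the features themselves
depend on the type assignment, the procedure iterates — featurize under
the current assignment, re-cluster, relabel — until the partition is
stable.  Clustering is agglomerative with average linkage and Euclidean
distance, cut at a user-chosen threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .core import ConnectomeGraph

__all__ = [
    "ConnectivityFeature",
    "TypeAssignment",
    "featurize",
    "feature_matrix",
    "cluster_features",
    "cblast_iterate",
    "embed_2d",
]


@dataclass
class ConnectivityFeature:
    body_id: int
    in_profile: np.ndarray   # sums to 1, or all zero if no inputs
    out_profile: np.ndarray
    isolated: bool           # no synaptic partners at all

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.in_profile, self.out_profile])


@dataclass
class TypeAssignment:
    labels: dict             # body_id → cluster label (int or str)
    iteration: int = 0
    converged: bool = False

    def vocabulary(self) -> list:
        return sorted(set(self.labels.values()), key=str)

    def partition_key(self) -> tuple:
        """Canonical form of the partition (invariant to label names)."""
        groups: dict = {}
        for bid in sorted(self.labels):
            groups.setdefault(self.labels[bid], []).append(bid)
        return tuple(sorted(tuple(g) for g in groups.values()))

    @classmethod
    def from_types(cls, g: ConnectomeGraph) -> "TypeAssignment":
        """Seed an assignment from the graph's cell-type labels
        (untyped neurons each get a singleton label)."""
        labels = {}
        for n, d in g.nx.nodes(data=True):
            labels[n] = d["type_name"] if d["type_name"] else f"__untyped_{n}"
        return cls(labels=labels)

    @classmethod
    def random(cls, g: ConnectomeGraph, n_clusters: int, seed: int) -> "TypeAssignment":
        """Uniform random labels over ``n_clusters``.  With n_clusters >=
        n_neurons this is a randomly-permuted singleton assignment — the
        recommended no-prior-knowledge start, since coarse random
        clusters mix the true types and erase the fingerprint signal."""
        rng = np.random.default_rng(seed)
        ids = sorted(g.body_ids())
        if n_clusters >= len(ids):
            return cls(labels={b: int(l)
                               for b, l in zip(ids, rng.permutation(len(ids)))})
        return cls(labels={b: int(l) for b, l in
                           zip(ids, rng.integers(0, n_clusters, len(ids)))})


def featurize(g: ConnectomeGraph, assignment: TypeAssignment,
              weighted: bool = True) -> list[ConnectivityFeature]:
    """Input/output connectivity fingerprints under ``assignment``.

    in_profile[t] = (synapse weight received from cluster-t partners) /
    (total input weight); out_profile analogous.  With
    ``weighted=False`` each partner contributes 1 regardless of synapse
    count (partner-count fingerprints) — much more robust to the
    heavy-tailed strength distribution when the assignment is still
    fine-grained, at the cost of ignoring strength information.  A side
    with no synapses is all-zero; a neuron with no partners at all is
    flagged isolated.
    """
    vocab = assignment.vocabulary()
    if not vocab:
        raise ValueError("empty cluster vocabulary")
    vidx = {t: i for i, t in enumerate(vocab)}
    k = len(vocab)
    feats = []
    for n in sorted(g.body_ids()):
        inp = np.zeros(k)
        outp = np.zeros(k)
        for u, _, d in g.nx.in_edges(n, data=True):
            inp[vidx[assignment.labels[u]]] += d["weight"] if weighted else 1
        for _, v, d in g.nx.out_edges(n, data=True):
            outp[vidx[assignment.labels[v]]] += d["weight"] if weighted else 1
        isolated = inp.sum() == 0 and outp.sum() == 0
        if inp.sum() > 0:
            inp /= inp.sum()
        if outp.sum() > 0:
            outp /= outp.sum()
        feats.append(ConnectivityFeature(body_id=n, in_profile=inp,
                                         out_profile=outp, isolated=isolated))
    return feats


def feature_matrix(features) -> np.ndarray:
    return np.vstack([f.vector for f in features])


def cluster_features(features, linkage_threshold: float,
                     seed: int = 0) -> TypeAssignment:
    """Agglomerative clustering (average linkage, Euclidean) of the
    fingerprints, cut at ``linkage_threshold``.  Deterministic given the
    inputs; ``seed`` is accepted for interface symmetry with the
    embedding and is unused here."""
    if not features:
        raise ValueError("no features to cluster")
    X = feature_matrix(features)
    if len(features) == 1:
        return TypeAssignment(labels={features[0].body_id: 0})
    if linkage_threshold <= 0:
        labels = np.arange(len(features))
    else:
        model = AgglomerativeClustering(
            n_clusters=None, distance_threshold=linkage_threshold,
            linkage="average", metric="euclidean")
        labels = model.fit_predict(X)
    return TypeAssignment(labels={f.body_id: int(l)
                                  for f, l in zip(features, labels)})


def cblast_iterate(g: ConnectomeGraph, initial: TypeAssignment,
                   linkage_threshold: float, max_iter: int = 20,
                   seed: int = 0, weighted: bool = True):
    """Iterative refinement: featurize → cluster → relabel until the
    partition stops changing or ``max_iter`` is reached.

    Returns ``(assignment, history)``; ``assignment.converged`` is False
    when the loop hit ``max_iter`` without a fixed point (not an error —
    oscillation between refinements can occur on ambiguous data).
    """
    history = [initial]
    current = initial
    for it in range(1, max_iter + 1):
        feats = featurize(g, current, weighted=weighted)
        nxt = cluster_features(feats, linkage_threshold, seed=seed)
        nxt.iteration = it
        history.append(nxt)
        if nxt.partition_key() == current.partition_key():
            nxt.converged = True
            return nxt, history
        current = nxt
    current.converged = False
    return current, history


def embed_2d(features, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP coordinates of the fingerprints, for visualization only
    (no downstream logic depends on them)."""
    import umap  # deferred: heavy import

    X = feature_matrix(features)
    n_neighbors = min(n_neighbors, max(2, len(features) - 1))
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=seed)
    return reducer.fit_transform(X)
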