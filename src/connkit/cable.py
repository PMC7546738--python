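"""Passive linear electrical model of a skeletonized neuron.

Each skeleton edge is represented as a truncated cone (frustum): the
axial resistance of an edge of length L with end radii r1, r2 is
Ra·L/(π·r1·r2), and its lateral membrane area π·(r1+r2)·√(L²+(r1−r2)²)
is split half to each endpoint node, giving per-node membrane
conductance (area/Rm) and capacitance (area·Cm).  A synaptic input is a
conductance transient (peak-normalized difference of exponentials)
linearized to a current source I(t) = g(t)·drive — valid in the
small-signal regime where the response is far from the reversal
potential.  Voltages are relative to rest.

Integration is implicit (backward Euler), unconditionally stable, with
the symmetric positive-definite system factorized once and a direct
sparse solve per step.

Parameters and units: Ra axial resistivity (Ω·m), Rm specific membrane
resistance (Ω·m²), Cm specific membrane capacitance (F/m², fixed at
0.01 in sweeps since it is set by membrane thickness); skeleton
geometry in μm; the public API uses ms and mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import factorized, splu
from scipy.spatial import cKDTree

from .core import Skeleton

__all__ = [
    "CableParameters",
    "CableSystem",
    "SynapticInput",
    "ResponseSummary",
    "CompartmentResponseModel",
    "build_cable",
    "simulate_response",
    "steady_state",
    "summarize_response",
    "compartment_matrices",
    "parameter_sweep",
    "nearest_nodes",
    "site_maps_from_table",
]

UM = 1e-6  # μm → m

DEFAULT_RA_VALUES = (0.4, 1.6, 4.0)    # Ω·m, spanning reported fly values
DEFAULT_RM_VALUES = (0.20, 0.83, 2.64)  # Ω·m²
FIXED_CM = 0.01                         # F/m²


@dataclass(frozen=True)
class CableParameters:
    Ra: float = 1.6     # axial resistivity, Ω·m
    Rm: float = 0.83    # specific membrane resistance, Ω·m²
    Cm: float = FIXED_CM  # specific membrane capacitance, F/m²

    def __post_init__(self):
        if self.Ra <= 0 or self.Rm <= 0 or self.Cm <= 0:
            raise ValueError("cable parameters must be strictly positive")


@dataclass(frozen=True)
class SynapticInput:
    """Typical synaptic input: 1 nS peak conductance, 0.1 ms rise and
    1 ms fall time constants, 60 mV drive (distance from rest to the
    reversal potential)."""
    site: int
    g_max: float = 1e-9       # S
    tau_rise_ms: float = 0.1
    tau_fall_ms: float = 1.0
    drive_mv: float = 60.0

    def __post_init__(self):
        if not self.tau_rise_ms < self.tau_fall_ms:
            raise ValueError("tau_rise must be < tau_fall")

    def current(self, t_ms: np.ndarray) -> np.ndarray:
        """Injected current (A) at times ``t_ms`` (ms), onset at t=0."""
        tr, tf = self.tau_rise_ms, self.tau_fall_ms
        t_peak = tr * tf / (tf - tr) * np.log(tf / tr)
        peak = np.exp(-t_peak / tf) - np.exp(-t_peak / tr)
        t = np.maximum(t_ms, 0.0)
        g = self.g_max * (np.exp(-t / tf) - np.exp(-t / tr)) / peak
        g[t_ms < 0] = 0.0
        return g * (self.drive_mv * 1e-3)


@dataclass
class CableSystem:
    """Discretized passive cable over a skeleton tree."""
    node_ids: list                   # skeleton node ids in matrix order
    laplacian: sparse.csr_matrix     # axial-conductance Laplacian (S)
    g_mem: np.ndarray                # per-node membrane conductance (S)
    c_mem: np.ndarray                # per-node membrane capacitance (F)
    regions: dict                    # node id → region label
    params: CableParameters
    index: dict = field(init=False)  # node id → matrix row

    def __post_init__(self):
        self.index = {n: i for i, n in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def total_membrane_area(self) -> float:
        """Total membrane area in m² (= Rm · Σ g_mem)."""
        return float(self.g_mem.sum() * self.params.Rm)


def build_cable(skel: Skeleton, params: CableParameters) -> CableSystem:
    """Discretize ``skel`` into a passive cable system (see module
    docstring for the frustum formulas)."""
    xyz = {k: v * UM for k, v in skel.coordinates().items()}
    radii = {k: v * UM for k, v in skel.radii().items()}
    node_ids = [int(i) for i in skel.nodes["node_id"]]
    index = {n: i for i, n in enumerate(node_ids)}
    n = len(node_ids)

    rows, cols, vals = [], [], []
    area = np.zeros(n)
    for u, v in skel.edge_list():
        L = float(np.linalg.norm(xyz[u] - xyz[v]))
        r1, r2 = radii[u], radii[v]
        if L == 0.0:
            raise ValueError(f"zero-length edge ({u}, {v}) with distinct endpoints")
        g_ax = np.pi * r1 * r2 / (params.Ra * L)
        i, j = index[u], index[v]
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-g_ax, -g_ax, g_ax, g_ax]
        a = np.pi * (r1 + r2) * np.hypot(L, r1 - r2)
        area[i] += a / 2
        area[j] += a / 2

    lap = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return CableSystem(
        node_ids=node_ids, laplacian=lap,
        g_mem=area / params.Rm, c_mem=area * params.Cm,
        regions=skel.labels(), params=params)


def simulate_response(cable: CableSystem, inputs, outputs,
                      dt_ms: float = 0.01, t_end_ms: float = 20.0) -> pd.DataFrame:
    """Simulate the voltage response to synaptic input(s).

    ``inputs``: a :class:`SynapticInput` or list of them (responses of
    the linear system superpose).  Returns a DataFrame with ``time_ms``
    and one mV column per requested output node (column name = node id).
    """
    if isinstance(inputs, SynapticInput):
        inputs = [inputs]
    tau_min = min(i.tau_rise_ms for i in inputs) if inputs else 1.0
    if dt_ms > tau_min / 5:
        raise ValueError(f"dt={dt_ms} ms too coarse: need dt <= tau_rise/5 "
                         f"= {tau_min / 5} ms")
    n = cable.n_nodes
    dt_s = dt_ms * 1e-3
    A = (sparse.diags(cable.c_mem / dt_s + cable.g_mem) + cable.laplacian).tocsc()
    solve = factorized(A)

    times = np.arange(0.0, t_end_ms + dt_ms / 2, dt_ms)
    currents = np.zeros((len(inputs), len(times)))
    sites = []
    for k, inp in enumerate(inputs):
        if inp.site not in cable.index:
            raise KeyError(f"input site {inp.site} not in cable")
        currents[k] = inp.current(times)
        sites.append(cable.index[inp.site])

    out_idx = [cable.index[o] for o in outputs]
    V = np.zeros(n)
    traces = np.zeros((len(times), len(out_idx)))
    for s in range(1, len(times)):
        rhs = cable.c_mem / dt_s * V
        for k, si in enumerate(sites):
            rhs[si] += currents[k, s]
        V = solve(rhs)
        if not np.all(np.isfinite(V)):
            raise RuntimeError(f"cable solve failed at t={times[s]} ms "
                               f"(dt={dt_ms} ms)")
        traces[s] = V[out_idx]

    df = pd.DataFrame(traces * 1e3, columns=[int(o) for o in outputs])
    df.insert(0, "time_ms", times)
    return df


def simulate_current(cable: CableSystem, site: int, current_fn, outputs,
                     dt_ms: float = 0.01, t_end_ms: float = 20.0) -> pd.DataFrame:
    """Simulate the response to an arbitrary injected current.

    ``current_fn(t_ms) -> A`` is evaluated on the time grid (a constant
    float is accepted for a step current switched on at t=0).  Same
    return format as :func:`simulate_response`.
    """
    n = cable.n_nodes
    dt_s = dt_ms * 1e-3
    A = (sparse.diags(cable.c_mem / dt_s + cable.g_mem) + cable.laplacian).tocsc()
    solve = factorized(A)
    times = np.arange(0.0, t_end_ms + dt_ms / 2, dt_ms)
    if callable(current_fn):
        currents = np.array([current_fn(t) for t in times], dtype=float)
    else:
        currents = np.full(len(times), float(current_fn))
        currents[0] = 0.0
    si = cable.index[site]
    out_idx = [cable.index[o] for o in outputs]
    V = np.zeros(n)
    traces = np.zeros((len(times), len(out_idx)))
    for s in range(1, len(times)):
        rhs = cable.c_mem / dt_s * V
        rhs[si] += currents[s]
        V = solve(rhs)
        if not np.all(np.isfinite(V)):
            raise RuntimeError(f"cable solve failed at t={times[s]} ms "
                               f"(dt={dt_ms} ms)")
        traces[s] = V[out_idx]
    df = pd.DataFrame(traces * 1e3, columns=[int(o) for o in outputs])
    df.insert(0, "time_ms", times)
    return df


def steady_state(cable: CableSystem, injections: dict) -> dict:
    """Steady-state voltages (mV) under sustained current injection.

    ``injections``: node id → current (A).  Solves (G_mem + L_axial)·V = I.
    """
    n = cable.n_nodes
    I = np.zeros(n)
    for node, amps in injections.items():
        I[cable.index[node]] = amps
    A = (sparse.diags(cable.g_mem) + cable.laplacian).tocsc()
    V = splu(A).solve(I)
    return {node: float(V[i] * 1e3) for node, i in cable.index.items()}


@dataclass
class ResponseSummary:
    delay_ms: float     # time of peak after input onset (NaN if no response)
    amplitude_mv: float


def summarize_response(times_ms, trace_mv, onset_ms: float = 0.0) -> ResponseSummary:
    """Peak amplitude and its latency relative to input onset; ties
    broken by the earliest time.  An identically-zero trace reports
    amplitude 0 and an undefined (NaN) delay."""
    trace = np.asarray(trace_mv, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    if not np.any(trace != 0.0):
        return ResponseSummary(delay_ms=float("nan"), amplitude_mv=0.0)
    i = int(np.argmax(trace))
    return ResponseSummary(delay_ms=float(times[i] - onset_ms),
                           amplitude_mv=float(trace[i]))


@dataclass
class CompartmentResponseModel:
    """Region-indexed response model: per (input region, output region)
    the mean delay and amplitude over sampled synapse pairs, with the
    residual SD of this matrix model against the raw pairs and of the
    single-scalar (one global mean) model.  By variance decomposition
    the matrix residual SD never exceeds the scalar one."""
    regions: list
    delay_matrix: pd.DataFrame       # ms; NaN where a region has no sites
    amplitude_matrix: pd.DataFrame   # mV
    delay_sd_matrix: float
    delay_sd_scalar: float
    amplitude_sd_matrix: float
    amplitude_sd_scalar: float
    absent_regions: list
    pairs: pd.DataFrame              # raw scatter: per sampled pair


def _group_sd(values, groups, group_means) -> float:
    resid = values - np.array([group_means[g] for g in groups])
    return float(np.sqrt(np.mean(resid ** 2)))


def compartment_matrices(cable: CableSystem, input_sites: dict,
                         output_sites: dict,
                         synapse: SynapticInput | None = None,
                         n_sample: int | None = None, seed: int = 0,
                         dt_ms: float = 0.02,
                         t_end_ms: float = 20.0) -> CompartmentResponseModel:
    """Region-to-region delay/amplitude matrices.

    ``input_sites`` / ``output_sites``: region → list of skeleton node
    ids (input = postsynaptic densities, output = presynaptic sites).
    ``n_sample`` caps the number of sites used per region on each side
    (without-replacement, seeded); None uses all sites, reproducing the
    exhaustive computation.  Regions present in neither map are flagged
    absent and their rows/columns are NaN.
    """
    if synapse is None:
        synapse = SynapticInput(site=-1)
    rng = np.random.default_rng(seed)
    regions = sorted(set(input_sites) | set(output_sites))
    absent = [r for r in regions
              if not input_sites.get(r) and not output_sites.get(r)]

    def pick(sites):
        sites = list(sites)
        if n_sample is not None and len(sites) > n_sample:
            return [int(s) for s in rng.choice(sites, size=n_sample, replace=False)]
        return sites

    ins = {r: pick(s) for r, s in input_sites.items() if s}
    outs = {r: pick(s) for r, s in output_sites.items() if s}
    all_outputs = [o for sites in outs.values() for o in sites]

    records = []
    for ri, in_nodes in ins.items():
        for node in in_nodes:
            tr = simulate_response(cable, replace(synapse, site=node),
                                   all_outputs, dt_ms=dt_ms, t_end_ms=t_end_ms)
            for rj, out_nodes in outs.items():
                for o in out_nodes:
                    s = summarize_response(tr["time_ms"], tr[o])
                    records.append({"input_region": ri, "output_region": rj,
                                    "input_node": node, "output_node": o,
                                    "delay_ms": s.delay_ms,
                                    "amplitude_mv": s.amplitude_mv})
    pairs = pd.DataFrame(records)
    if pairs.empty:
        raise ValueError("no (input, output) site pairs to evaluate")

    delay_mat = pd.DataFrame(np.nan, index=regions, columns=regions)
    amp_mat = pd.DataFrame(np.nan, index=regions, columns=regions)
    gmeans_d, gmeans_a = {}, {}
    for (ri, rj), grp in pairs.groupby(["input_region", "output_region"]):
        gmeans_d[(ri, rj)] = grp["delay_ms"].mean()
        gmeans_a[(ri, rj)] = grp["amplitude_mv"].mean()
        delay_mat.loc[ri, rj] = gmeans_d[(ri, rj)]
        amp_mat.loc[ri, rj] = gmeans_a[(ri, rj)]

    keys = list(zip(pairs["input_region"], pairs["output_region"]))
    d = pairs["delay_ms"].to_numpy()
    a = pairs["amplitude_mv"].to_numpy()
    return CompartmentResponseModel(
        regions=regions, delay_matrix=delay_mat, amplitude_matrix=amp_mat,
        delay_sd_matrix=_group_sd(d, keys, gmeans_d),
        delay_sd_scalar=float(np.sqrt(np.mean((d - d.mean()) ** 2))),
        amplitude_sd_matrix=_group_sd(a, keys, gmeans_a),
        amplitude_sd_scalar=float(np.sqrt(np.mean((a - a.mean()) ** 2))),
        absent_regions=absent, pairs=pairs)


def parameter_sweep(skel: Skeleton, input_sites: dict, output_sites: dict,
                    Ra_values=DEFAULT_RA_VALUES, Rm_values=DEFAULT_RM_VALUES,
                    **kwargs) -> dict:
    """Grid evaluation over (Ra, Rm), Cm fixed: one
    :class:`CompartmentResponseModel` per combination (9 by default,
    min/medium/max of each resistance — both are needed because the two
    resistances interact non-linearly)."""
    models = {}
    for Ra in Ra_values:
        for Rm in Rm_values:
            cable = build_cable(skel, CableParameters(Ra=Ra, Rm=Rm))
            models[(Ra, Rm)] = compartment_matrices(
                cable, input_sites, output_sites, **kwargs)
    return models


def nearest_nodes(skel: Skeleton, xyz: np.ndarray) -> np.ndarray:
    """Map 3-D points (μm) to their nearest skeleton nodes (Euclidean)."""
    coords = skel.nodes[["x", "y", "z"]].to_numpy()
    tree = cKDTree(coords)
    _, idx = tree.query(np.atleast_2d(xyz))
    return skel.nodes["node_id"].to_numpy()[idx]


def site_maps_from_table(skel: Skeleton, synapses: pd.DataFrame):
    """Build (input_sites, output_sites) region→node maps from a synapse
    table with columns x, y, z, kind (pre|post), roi.  Post-synaptic
    densities are inputs; presynaptic sites are outputs."""
    nodes = nearest_nodes(skel, synapses[["x", "y", "z"]].to_numpy())
    ins: dict[str, list] = {}
    outs: dict[str, list] = {}
    for node, kind, roi in zip(nodes, synapses["kind"], synapses["roi"]):
        target = ins if kind == "post" else outs
        target.setdefault(str(roi), []).append(int(node))
    return ins, outs
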