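"""Compartment statistics against brute-force oracles, strength-fit
round trips, and completeness arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import floyd_warshall

import connkit as ck
from conftest import random_graph


def oracle_summary(g):
    """Independent all-pairs reference via dense Floyd–Warshall."""
    ids = sorted(g.body_ids())
    idx = {b: i for i, b in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    W = {}
    for u, v, w, _ in g.edges():
        A[idx[u], idx[v]] = 1
        W[(u, v)] = w
    D = floyd_warshall(A, directed=True, unweighted=True)
    finite = np.isfinite(D) & ~np.eye(n, dtype=bool)
    recip = [w for (u, v), w in W.items() if (v, u) in W]
    nonrecip = [w for (u, v), w in W.items() if (v, u) not in W]
    partners = []
    for i in range(n):
        partners.append(len(set(np.nonzero(A[i])[0]) | set(np.nonzero(A[:, i])[0])))
    return {
        "n_neurons": n,
        "n_connections": len(W),
        "k_avg": float(np.mean(partners)),
        "diameter": int(D[finite].max()) if finite.any() else 0,
        "avg_dist": float(D[finite].mean()) if finite.any() else float("nan"),
        "frac_recip": len(recip) / len(W) if W else 0.0,
        "str_recip": float(np.mean(recip)) if recip else float("nan"),
        "str_nonrecip": float(np.mean(nonrecip)) if nonrecip else float("nan"),
        "n_unreachable_pairs": int(n * (n - 1) - finite.sum()),
    }


def oracle_path_curve(g, threshold):
    """Matrix-power reachability: frac of pairs reachable in <= h hops."""
    gt = ck.threshold_graph(g, threshold)
    ids = sorted(gt.body_ids())
    idx = {b: i for i, b in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n), dtype=bool)
    for u, v, _, _ in gt.edges():
        A[idx[u], idx[v]] = True
    reach = np.zeros((n, n), dtype=bool)
    P = np.eye(n, dtype=bool)
    fracs = []
    for _ in range(n):
        P = (P @ A) != 0
        reach |= P
        off = reach & ~np.eye(n, dtype=bool)
        fracs.append(off.sum() / (n * (n - 1)))
    return fracs


class TestCompartmentSummary:
    def test_bidirectional_triangle(self):
        g = ck.ConnectomeGraph()
        for i in (1, 2, 3):
            g.add_neuron(i)
        for u in (1, 2, 3):
            for v in (1, 2, 3):
                if u != v:
                    g.add_edge(u, v, 1)
        s = ck.compartment_summary(g)
        assert (s.n_neurons, s.n_connections) == (3, 6)
        assert s.k_avg == 2 and s.diameter == 1
        assert s.frac_recip == 1.0 and s.avg_dist == 1.0
        assert s.n_unreachable_pairs == 0

    def test_directed_three_cycle(self):
        g = ck.ConnectomeGraph()
        for i in (1, 2, 3):
            g.add_neuron(i)
        g.add_edge(1, 2, 1)
        g.add_edge(2, 3, 1)
        g.add_edge(3, 1, 1)
        s = ck.compartment_summary(g)
        assert s.n_connections == 3 and s.frac_recip == 0.0
        assert s.diameter == 2 and s.avg_dist == 1.5

    def test_empty_graph_is_error(self):
        with pytest.raises(ValueError):
            ck.compartment_summary(ck.ConnectomeGraph())

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("n,p", [(30, 0.15), (12, 0.35)])
    def test_matches_floyd_warshall_oracle(self, n, p, seed):
        g = random_graph(n, p, seed)
        if g.n_edges == 0:
            return
        s = ck.compartment_summary(g)
        o = oracle_summary(g)
        for key, want in o.items():
            got = getattr(s, key)
            if isinstance(want, float) and np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want), key


class TestPathCurve:
    def test_chain(self, chain_graph):
        (curve,) = ck.path_length_curve(chain_graph, [1])
        assert curve.points[0] == (0, pytest.approx(2 / 6))
        assert curve.points[1] == (1, pytest.approx(3 / 6))

    def test_complete_digraph(self):
        g = ck.generate_connectome(ck.GeneratorConfig(
            n_neurons=5, p_conn=1.0, reciprocity_boost=1.0, seed=0))
        (curve,) = ck.path_length_curve(g, [1])
        assert curve.points[0] == (0, 1.0)

    def test_monotone_and_bounded(self):
        g = random_graph(20, 0.2, 3)
        for curve in ck.path_length_curve(g, [1, 3, 5]):
            fr = [f for _, f in curve.points]
            assert all(b >= a for a, b in zip(fr, fr[1:]))
            assert all(0.0 <= f <= 1.0 for f in fr)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_matrix_power_oracle(self, seed):
        g = random_graph(25, 0.12, seed, w_max=8)
        for thr in (1, 3):
            (curve,) = ck.path_length_curve(g, [thr])
            oracle = oracle_path_curve(g, thr)
            for k, frac in curve.points:
                assert frac == pytest.approx(oracle[k])
            # beyond the last reported point the oracle stays flat
            if curve.points:
                assert oracle[-1] == pytest.approx(curve.points[-1][1])


class TestFitStrengthDistribution:
    def test_recovers_generator_parameters(self):
        w = ck.sample_strengths(1.67, 42.0, 100, 300_000, seed=10)
        fit = ck.fit_strength_distribution(w, 1, 100)
        assert fit.gamma == pytest.approx(1.67, abs=0.05)
        assert fit.kappa == pytest.approx(42.0, abs=3.0)
        assert fit.n_used == 300_000 and fit.n_excluded == 0

    def test_geometric_limit_gives_gamma_near_zero(self):
        # gamma=0 reduces the model to a truncated geometric distribution
        w = ck.sample_strengths(0.0, 10.0, 100, 200_000, seed=11)
        fit = ck.fit_strength_distribution(w, 1, 100)
        assert abs(fit.gamma) < 0.05
        assert fit.kappa == pytest.approx(10.0, rel=0.05)

    def test_self_consistency_across_seeds(self):
        # generator -> fitter round trip across seeds stays within
        # Monte-Carlo error of the generating parameters
        gammas, kappas = [], []
        for seed in range(10):
            w = ck.sample_strengths(1.67, 42.0, 100, 50_000, seed=seed)
            fit = ck.fit_strength_distribution(w, 1, 100)
            gammas.append(fit.gamma)
            kappas.append(fit.kappa)
        assert np.mean(gammas) == pytest.approx(1.67, abs=0.03)
        assert np.mean(kappas) == pytest.approx(42.0, abs=2.0)

    def test_out_of_range_weights_counted(self):
        w = np.concatenate([ck.sample_strengths(1.67, 42.0, 100, 5000, 1),
                            [150, 200, 300]])
        fit = ck.fit_strength_distribution(w, 1, 100)
        assert fit.n_excluded == 3

    def test_degenerate_input_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            ck.fit_strength_distribution([5] * 100, 1, 100)


class TestDetectionProbability:
    def test_paper_case_exceeds_999(self):
        assert ck.detection_probability(10, 0.5) == pytest.approx(0.9990234375)

    @pytest.mark.parametrize("c", [0.1, 0.5, 0.9])
    def test_single_synapse_identity(self, c):
        assert ck.detection_probability(1, c) == pytest.approx(c)

    def test_certain_tracing(self):
        assert ck.detection_probability(7, 1.0) == 1.0

    def test_strictly_increasing(self):
        ns = [1, 2, 5, 10, 20]
        ps = [ck.detection_probability(n, 0.3) for n in ns]
        assert all(b > a for a, b in zip(ps, ps[1:]))
        rates = [0.1, 0.3, 0.5, 0.7, 0.9]
        qs = [ck.detection_probability(5, r) for r in rates]
        assert all(b > a for a, b in zip(qs, qs[1:]))

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            ck.detection_probability(5, 1.5)


class TestCompletenessDelta:
    def test_identical_graphs_all_zero(self, tiny_graph):
        table, summary = ck.completeness_delta(tiny_graph, tiny_graph)
        assert (table["w_before"] == table["w_after"]).all()
        assert summary["increased"] == summary["decreased"] == 0

    def test_subsampled_graph_never_decreases(self):
        full = ck.generate_connectome(ck.GeneratorConfig(n_neurons=40, seed=6))
        rng = np.random.default_rng(0)
        sub = ck.ConnectomeGraph(full.regions)
        for n, d in full.nx.nodes(data=True):
            sub.add_neuron(n, d["type_name"], d["instance"], d["roi_counts"])
        for u, v, w, _ in full.edges():
            w2 = int(rng.binomial(w, 0.6))
            if w2 > 0:
                sub.add_edge(u, v, w2)
        table, summary = ck.completeness_delta(sub, full)
        assert summary["decreased"] == 0

    def test_disjoint_graphs_all_new(self, chain_graph):
        reverse = ck.ConnectomeGraph()
        for i in (1, 2, 3):
            reverse.add_neuron(i)
        reverse.add_edge(2, 1, 12)
        reverse.add_edge(3, 2, 4)
        table, summary = ck.completeness_delta(chain_graph, reverse)
        assert (table["w_before"] == 0).sum() == reverse.n_edges
        assert (table["w_after"] == 0).sum() == chain_graph.n_edges
        assert summary["new_strong"] == 1  # the 12-synapse pair


class TestAccuracyArithmetic:
    def test_psds_per_tbar(self):
        assert ck.mean_psds_per_tbar(64e6, 9.5e6) == pytest.approx(6.7, abs=0.05)

    def test_both_wrong(self):
        assert ck.both_wrong_probability(0.79) == pytest.approx(0.0441)
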