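"""Passive cable model against closed-form RC and cable-theory solutions."""

import numpy as np
import pandas as pd
import pytest

import connkit as ck
from connkit.cable import (CableSystem, simulate_current, steady_state,
                           DEFAULT_RA_VALUES, DEFAULT_RM_VALUES)
from scipy import sparse


def cylinder_skeleton(n_nodes, length_um, radius_um, label="A"):
    """Straight uniform cylinder along x."""
    xs = np.linspace(0.0, length_um, n_nodes)
    nodes = pd.DataFrame({
        "node_id": range(1, n_nodes + 1), "struct_type": [0] * n_nodes,
        "x": xs, "y": [0.0] * n_nodes, "z": [0.0] * n_nodes,
        "radius": [radius_um] * n_nodes,
        "parent_id": [-1] + list(range(1, n_nodes)),
        "label": [label] * n_nodes,
    })
    return ck.Skeleton(nodes)


def single_compartment(g_mem, c_mem):
    """Isoelectric one-node system built directly."""
    return CableSystem(node_ids=[1], laplacian=sparse.csr_matrix((1, 1)),
                       g_mem=np.array([g_mem]), c_mem=np.array([c_mem]),
                       regions={1: "A"}, params=ck.CableParameters())


class TestBuildCable:
    def test_cylinder_axial_resistance(self):
        # Ra=1 Ω·m, L=100 μm, r=0.5 μm -> R = Ra L / (π r²) ≈ 1.273e8 Ω
        skel = cylinder_skeleton(2, 100.0, 0.5)
        cable = ck.build_cable(skel, ck.CableParameters(Ra=1.0, Rm=1.0))
        g_ax = -cable.laplacian[0, 1]
        expected_R = 1.0 * 100e-6 / (np.pi * (0.5e-6) ** 2)
        assert 1 / g_ax == pytest.approx(expected_R, rel=1e-12)
        assert 1 / g_ax == pytest.approx(1.273e8, rel=1e-3)

    def test_frustum_reduces_to_cylinder(self):
        # equal end radii: axial conductance = π r² / (Ra L) exactly
        skel = cylinder_skeleton(3, 50.0, 0.4)
        cable = ck.build_cable(skel, ck.CableParameters(Ra=2.0, Rm=1.0))
        g01 = cable.laplacian[0, 0] - (-cable.laplacian[0, 1]) * 0  # diag sanity
        g_expected = np.pi * (0.4e-6) ** 2 / (2.0 * 25e-6)
        assert -cable.laplacian[0, 1] == pytest.approx(g_expected)

    def test_total_membrane_area_is_frustum_sum(self):
        skel = ck.generate_skeleton(2, 20, 60.0, (0.2, 1.0), seed=1)
        params = ck.CableParameters()
        cable = ck.build_cable(skel, params)
        xyz = {k: v * 1e-6 for k, v in skel.coordinates().items()}
        rad = {k: v * 1e-6 for k, v in skel.radii().items()}
        total = 0.0
        for u, v in skel.edge_list():
            L = np.linalg.norm(xyz[u] - xyz[v])
            r1, r2 = rad[u], rad[v]
            total += np.pi * (r1 + r2) * np.hypot(L, r1 - r2)
        assert cable.total_membrane_area() == pytest.approx(total, rel=1e-9)

    def test_zero_length_edge_is_error(self):
        nodes = pd.DataFrame({
            "node_id": [1, 2], "struct_type": [0, 0],
            "x": [0.0, 0.0], "y": [0.0, 0.0], "z": [0.0, 0.0],
            "radius": [0.5, 0.5], "parent_id": [-1, 1], "label": ["A", "A"]})
        with pytest.raises(ValueError, match="zero-length"):
            ck.build_cable(ck.Skeleton(nodes), ck.CableParameters())


class TestSimulateResponse:
    def test_zero_conductance_gives_zero_trace(self):
        skel = cylinder_skeleton(10, 50.0, 0.5)
        cable = ck.build_cable(skel, ck.CableParameters())
        inp = ck.SynapticInput(site=1, g_max=0.0)
        tr = ck.simulate_response(cable, inp, [5, 10], dt_ms=0.02, t_end_ms=2.0)
        assert np.allclose(tr[5], 0.0) and np.allclose(tr[10], 0.0)

    def test_rc_step_response_closed_form(self):
        # V(t) = I0 R (1 - exp(-t/RC)); check within 0.5% at t = RC
        R, C = 1e9, 20e-12   # 1 GΩ, 20 pF -> tau = 20 ms
        cable = single_compartment(1 / R, C)
        I0 = 10e-12
        tau_ms = R * C * 1e3
        tr = simulate_current(cable, 1, I0, [1], dt_ms=0.005,
                              t_end_ms=tau_ms * 1.05)
        t = tr["time_ms"].to_numpy()
        idx = int(np.argmin(np.abs(t - tau_ms)))
        expected = I0 * R * (1 - np.exp(-1)) * 1e3  # mV
        assert tr[1].iloc[idx] == pytest.approx(expected, rel=5e-3)

    def test_sealed_end_cable_attenuation(self):
        # steady state V(x)/V(0) = cosh((l-x)/λ)/cosh(l/λ)
        Ra, Rm = 1.6, 0.83
        r = 0.5e-6
        lam = np.sqrt(Rm * r / (2 * Ra))       # ≈ 360 μm
        l_um = 500.0
        n = 201                                 # 200 segments
        skel = cylinder_skeleton(n, l_um, 0.5)
        cable = ck.build_cable(skel, ck.CableParameters(Ra=Ra, Rm=Rm))
        V = steady_state(cable, {1: 1e-12})
        xs = np.linspace(0.0, l_um * 1e-6, n)
        expected = np.cosh((l_um * 1e-6 - xs) / lam) / np.cosh(l_um * 1e-6 / lam)
        got = np.array([V[i + 1] for i in range(n)]) / V[1]
        assert np.max(np.abs(got - expected)) < 0.01

    def test_superposition(self):
        skel = ck.generate_skeleton(2, 15, 50.0, (0.2, 0.8), seed=4)
        cable = ck.build_cable(skel, ck.CableParameters())
        a = ck.SynapticInput(site=1)
        b = ck.SynapticInput(site=10, g_max=2e-9)
        out = [5, 12]
        ta = ck.simulate_response(cable, a, out, dt_ms=0.02, t_end_ms=5.0)
        tb = ck.simulate_response(cable, b, out, dt_ms=0.02, t_end_ms=5.0)
        tab = ck.simulate_response(cable, [a, b], out, dt_ms=0.02, t_end_ms=5.0)
        for o in out:
            combined = ta[o] + tb[o]
            scale = np.abs(tab[o]).max()
            assert np.allclose(tab[o], combined, atol=scale * 1e-9)

    def test_transfer_reciprocity(self):
        # passive symmetric network: amplitude a->b equals b->a for the
        # same injected current waveform
        skel = ck.generate_skeleton(3, 20, 80.0, (0.1, 0.9), seed=6)
        cable = ck.build_cable(skel, ck.CableParameters())
        a, b = 3, 55
        t_ab = ck.simulate_response(cable, ck.SynapticInput(site=a), [b],
                                    dt_ms=0.02, t_end_ms=10.0)
        t_ba = ck.simulate_response(cable, ck.SynapticInput(site=b), [a],
                                    dt_ms=0.02, t_end_ms=10.0)
        assert np.allclose(t_ab[b], t_ba[a], rtol=1e-9, atol=1e-12)

    def test_dt_refinement_converges(self):
        skel = cylinder_skeleton(30, 100.0, 0.5)
        cable = ck.build_cable(skel, ck.CableParameters())
        inp = ck.SynapticInput(site=1)
        peaks = []
        for dt in (0.02, 0.01):
            tr = ck.simulate_response(cable, inp, [15], dt_ms=dt, t_end_ms=10.0)
            peaks.append(tr[15].max())
        assert abs(peaks[1] - peaks[0]) < 0.005 * abs(peaks[1])

    def test_coarse_dt_rejected(self):
        skel = cylinder_skeleton(5, 20.0, 0.5)
        cable = ck.build_cable(skel, ck.CableParameters())
        with pytest.raises(ValueError, match="dt"):
            ck.simulate_response(cable, ck.SynapticInput(site=1), [3],
                                 dt_ms=0.5)


class TestSummarizeResponse:
    def test_unique_peak(self):
        t = np.linspace(0, 10, 101)
        trace = np.exp(-((t - 3) ** 2))
        s = ck.summarize_response(t, trace)
        assert s.delay_ms == pytest.approx(3.0, abs=0.1)
        assert s.amplitude_mv == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_trace(self):
        s = ck.summarize_response(np.arange(5.0), np.zeros(5))
        assert s.amplitude_mv == 0.0 and np.isnan(s.delay_ms)

    def test_tie_broken_earliest(self):
        t = np.arange(5.0)
        s = ck.summarize_response(t, np.array([0, 1, 2, 2, 1.0]))
        assert s.delay_ms == 2.0

    def test_discretized_rc_peak_within_dt(self):
        cable = single_compartment(1e-9, 20e-12)
        inp = ck.SynapticInput(site=1)
        dt = 0.01
        tr = ck.simulate_response(cable, inp, [1], dt_ms=dt, t_end_ms=20.0)
        s = ck.summarize_response(tr["time_ms"], tr[1])
        # semi-analytic peak of the biexponential filtered through RC,
        # computed by fine independent quadrature of the convolution
        tf = np.arange(0, 20.0, 0.0005)
        I = inp.current(tf)
        R, C = 1e9, 20e-12
        tauRC_ms = R * C * 1e3
        kernel = np.exp(-tf / tauRC_ms) / C * 0.0005e-3
        V = np.convolve(I, kernel)[:len(tf)] * 1e3
        t_peak = tf[np.argmax(V)]
        assert abs(s.delay_ms - t_peak) <= 2 * dt


@pytest.fixture(scope="module")
def three_region():
    skel = ck.generate_skeleton(3, 30, 150.0, (0.1, 1.0), seed=2)
    cable = ck.build_cable(skel, ck.CableParameters())
    by_region = {}
    for n, l in skel.labels().items():
        by_region.setdefault(l, []).append(n)
    ins = {r: v[:5] for r, v in by_region.items()}
    outs = {r: v[5:10] for r, v in by_region.items()}
    return skel, cable, ins, outs


class TestCompartmentMatrices:

    def test_within_region_faster_and_larger(self, three_region):
        _, cable, ins, outs = three_region
        m = ck.compartment_matrices(cable, ins, outs, n_sample=4, seed=0)
        D, A = m.delay_matrix, m.amplitude_matrix
        regions = m.regions
        within_d = [D.loc[r, r] for r in regions]
        cross_d = [D.loc[a, b] for a in regions for b in regions if a != b]
        assert max(within_d) < min(cross_d)
        within_a = [A.loc[r, r] for r in regions]
        cross_a = [A.loc[a, b] for a in regions for b in regions if a != b]
        assert min(within_a) > max(cross_a)

    def test_matrix_residual_never_worse(self, three_region):
        _, cable, ins, outs = three_region
        m = ck.compartment_matrices(cable, ins, outs, n_sample=4, seed=0)
        assert m.delay_sd_matrix <= m.delay_sd_scalar
        assert m.amplitude_sd_matrix <= m.amplitude_sd_scalar

    def test_full_sample_reproduces_exhaustive(self, three_region):
        _, cable, ins, outs = three_region
        small_ins = {r: v[:2] for r, v in ins.items()}
        small_outs = {r: v[:2] for r, v in outs.items()}
        m_all = ck.compartment_matrices(cable, small_ins, small_outs,
                                        n_sample=None, seed=0)
        m_cap = ck.compartment_matrices(cable, small_ins, small_outs,
                                        n_sample=99, seed=5)
        pd.testing.assert_frame_equal(m_all.delay_matrix, m_cap.delay_matrix)


class TestParameterSweep:
    def test_nine_models_and_monotone_rm(self):
        skel = ck.generate_skeleton(2, 12, 60.0, (0.2, 0.8), seed=3)
        by_region = {}
        for n, l in skel.labels().items():
            by_region.setdefault(l, []).append(n)
        ins = {r: v[:2] for r, v in by_region.items()}
        outs = {r: v[2:4] for r, v in by_region.items()}
        models = ck.parameter_sweep(skel, ins, outs, n_sample=2, seed=0,
                                    dt_ms=0.02, t_end_ms=10.0)
        assert len(models) == 9
        assert set(k[0] for k in models) == set(DEFAULT_RA_VALUES)
        # steady-state (and hence peak) amplitude rises with Rm at fixed Ra
        for Ra in DEFAULT_RA_VALUES:
            amps = [models[(Ra, Rm)].amplitude_matrix.mean().mean()
                    for Rm in DEFAULT_RM_VALUES]
            assert amps[0] < amps[1] < amps[2]

    def test_sweep_deterministic(self):
        skel = ck.generate_skeleton(2, 10, 50.0, (0.2, 0.8), seed=4)
        by_region = {}
        for n, l in skel.labels().items():
            by_region.setdefault(l, []).append(n)
        ins = {r: v[:3] for r, v in by_region.items()}
        outs = {r: v[3:5] for r, v in by_region.items()}
        kw = dict(Ra_values=(1.6,), Rm_values=(0.83,), n_sample=2, seed=9,
                  dt_ms=0.02, t_end_ms=5.0)
        m1 = ck.parameter_sweep(skel, ins, outs, **kw)
        m2 = ck.parameter_sweep(skel, ins, outs, **kw)
        pd.testing.assert_frame_equal(m1[(1.6, 0.83)].delay_matrix,
                                      m2[(1.6, 0.83)].delay_matrix)


class TestCableParameters:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            ck.CableParameters(Ra=-1.0)

    def test_synaptic_input_tau_ordering(self):
        with pytest.raises(ValueError):
            ck.SynapticInput(site=1, tau_rise_ms=2.0, tau_fall_ms=1.0)
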