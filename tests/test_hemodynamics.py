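"""Reduced-order flow network: resistances, solver, features.

The independent oracle for the solver is recursive series/parallel resistance
reduction on trees — a different algorithm from the nodal linear solve it
checks.
"""

import numpy as np
import pytest

from fvs3d import hemodynamics as hemo
from fvs3d.hemodynamics import (
    FlowEdge,
    FlowNetwork,
    build_flow_network,
    extract_hemo_features,
    inlet_waveform,
    mass_conservation_residual,
    poiseuille_resistance,
    solve_network,
)
from fvs3d.profiling import CenterlineProfile, ProfiledSegment


def profile_from_edges(edges, radii_px=None):
    """Fabricate a CenterlineProfile whose segments realize given edges.

    ``edges``: list of (node_a, node_b, length_px, radius_px).
    """
    segs = []
    for i, (a, b, L, r) in enumerate(edges):
        n = max(int(L) + 1, 2)
        pts = np.stack([np.full(n, float(i * 40)),
                        np.linspace(0, L, n)], axis=1)
        tangents = np.tile([0.0, 1.0], (n, 1))
        normals = np.tile([1.0, 0.0], (n, 1))
        segs.append(ProfiledSegment(i, a, b, pts, tangents, normals,
                                    np.full(n, float(r)), np.zeros(n, bool)))
    return CenterlineProfile(segs, px_size=1.0, shape=(400, 400))


def tree_oracle(net: FlowNetwork, q_in: float):
    """Series/parallel reduction: equivalent resistance of every subtree,
    then top-down flow splitting.  Valid for tree topologies with all
    outlets at the same boundary pressure."""
    children = {}
    for k, e in enumerate(net.edges):
        children.setdefault(e.node_a, []).append((k, e.node_b))
        children.setdefault(e.node_b, []).append((k, e.node_a))

    def subtree_resistance(node, come_from_edge):
        branch = [(k, other) for k, other in children.get(node, [])
                  if k != come_from_edge]
        if not branch:
            return 0.0
        inv = 0.0
        for k, other in branch:
            r_down = net.edges[k].resistance + subtree_resistance(other, k)
            inv += 1.0 / r_down
        return 1.0 / inv

    flows = {}
    pressures = {n: None for n in net.nodes}

    def push(node, come_from_edge, q, p_here):
        pressures[node] = p_here
        branch = [(k, other) for k, other in children.get(node, [])
                  if k != come_from_edge]
        if not branch:
            return
        rs = [net.edges[k].resistance + subtree_resistance(other, k)
              for k, other in branch]
        inv_total = sum(1.0 / r for r in rs)
        for (k, other), r in zip(branch, rs):
            qk = q * (1.0 / r) / inv_total
            flows[k] = qk
            push(other, k, qk, p_here - qk * net.edges[k].resistance)

    r_total = subtree_resistance(net.inlet, None)
    push(net.inlet, None, q_in, net.outlet_pressure + q_in * r_total)
    return flows, pressures


class TestBuildNetwork:
    def test_poiseuille_closed_form(self):
        # mu=0.035, L=1 cm, r=0.01 cm -> 8*0.035*1/(pi*1e-8)
        R = poiseuille_resistance(1.0, 0.01, 0.035)
        assert R == pytest.approx(8 * 0.035 / (np.pi * 1e-8), rel=1e-12)
        assert R == pytest.approx(8.913e6, rel=1e-3)

    def test_series_resistance_doubles(self):
        p = profile_from_edges([(0, 1, 100, 5), (1, 2, 100, 5)])
        net = build_flow_network(p, inlet_node=0)
        t, q = inlet_waveform(T=16, shape="constant", peak_flow=1.0)
        sol = solve_network(net, (t, q))
        drop = sol.face_pressure[0, 0] - net.outlet_pressure
        assert drop == pytest.approx(2 * net.edges[0].resistance, rel=1e-9)

    def test_parallel_resistance_halves(self):
        # two identical edges between the same pair of nodes
        p = profile_from_edges([(0, 1, 100, 5), (0, 1, 100, 5), (1, 2, 1, 50)])
        net = build_flow_network(p, inlet_node=0)
        t, q = inlet_waveform(T=4, shape="constant", peak_flow=1.0)
        sol = solve_network(net, (t, q))
        r_par = sol.node_pressure[0, 0] - sol.node_pressure[1, 0]
        assert r_par == pytest.approx(net.edges[0].resistance / 2, rel=1e-9)

    def test_disconnected_graph_rejected(self):
        p = profile_from_edges([(0, 1, 50, 5), (2, 3, 50, 5)])
        with pytest.raises(ValueError, match="disconnected"):
            build_flow_network(p)

    def test_default_inlet_is_widest_terminal(self):
        p = profile_from_edges([(0, 1, 50, 8), (1, 2, 50, 4), (1, 3, 50, 4)])
        net = build_flow_network(p)
        assert net.inlet == 0
        assert sorted(net.outlets) == [2, 3]


class TestWaveform:
    def test_half_sine_peak_at_midpoint(self):
        t, q = inlet_waveform(T=21, period=1.0, peak_flow=2.0)
        assert int(np.argmax(q)) == 10
        assert q.max() == pytest.approx(2.0)

    def test_constant_shape(self):
        _, q = inlet_waveform(T=8, shape="constant", peak_flow=0.5)
        assert np.allclose(q, 0.5)

    def test_pulse_volume_matches_analytic_integral(self):
        # integral of peak*sin(pi t / P) over [0, P] = 2*peak*P/pi
        t, q = inlet_waveform(T=100, period=1.0, peak_flow=1.0)
        vol = np.trapezoid(q, t)
        assert vol == pytest.approx(2.0 / np.pi, rel=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            inlet_waveform(T=1)
        with pytest.raises(ValueError):
            inlet_waveform(peak_flow=0.0)


class TestSolve:
    def test_single_tube_pressure_drop_exact(self):
        p = profile_from_edges([(0, 1, 200, 6)])
        net = build_flow_network(p, inlet_node=0)
        t, q = inlet_waveform(T=20)
        sol = solve_network(net, (t, q))
        R = net.edges[0].resistance
        drops = sol.face_pressure[0] - net.outlet_pressure
        assert np.allclose(drops, q * R, rtol=1e-9)

    def test_symmetric_bifurcation_splits_half(self):
        p = profile_from_edges([(0, 1, 100, 8), (1, 2, 80, 5), (1, 3, 80, 5)])
        net = build_flow_network(p, inlet_node=0)
        t, q = inlet_waveform(T=10)
        sol = solve_network(net, (t, q))
        assert np.allclose(sol.face_flow[1], q / 2, rtol=1e-9)
        assert np.allclose(sol.face_flow[2], q / 2, rtol=1e-9)

    def test_asymmetric_tree_matches_reduction_oracle(self):
        edges = [(0, 1, 120, 8),
                 (1, 2, 90, 6), (1, 3, 60, 4),
                 (2, 4, 70, 5), (2, 5, 110, 3),
                 (3, 6, 40, 3), (3, 7, 95, 2)]
        net = build_flow_network(profile_from_edges(edges), inlet_node=0)
        q_in = 0.37
        t, q = inlet_waveform(T=3, shape="constant", peak_flow=q_in)
        sol = solve_network(net, (t, q))
        flows, pressures = tree_oracle(net, q_in)
        for k in range(len(net.edges)):
            assert sol.edge_flow[k, 0] == pytest.approx(flows[k], rel=1e-9)
        idx = {n: i for i, n in enumerate(net.nodes)}
        for n, p_ in pressures.items():
            assert sol.node_pressure[idx[n], 0] == pytest.approx(p_, rel=1e-9)

    def test_random_trees_mass_conserved_and_match_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            # random binary tree with 3 levels
            edges = [(0, 1, rng.uniform(40, 150), rng.uniform(4, 9))]
            nxt = 2
            frontier = [1]
            for _ in range(2):
                new = []
                for node in frontier:
                    for _ in range(2):
                        edges.append((node, nxt, rng.uniform(30, 120),
                                      rng.uniform(2, 6)))
                        new.append(nxt)
                        nxt += 1
                frontier = new
            net = build_flow_network(profile_from_edges(edges), inlet_node=0)
            t, q = inlet_waveform(T=5)
            sol = solve_network(net, (t, q))
            assert mass_conservation_residual(sol) <= 1e-9
            flows, _ = tree_oracle(net, float(q[2]))
            for k in range(len(net.edges)):
                assert sol.edge_flow[k, 2] == pytest.approx(flows[k], rel=1e-9)

    def test_pressure_decreases_along_flow_direction(self):
        edges = [(0, 1, 100, 8), (1, 2, 80, 5), (1, 3, 80, 4), (3, 4, 50, 3)]
        net = build_flow_network(profile_from_edges(edges), inlet_node=0)
        t, q = inlet_waveform(T=6)
        sol = solve_network(net, (t, q))
        idx = {n: i for i, n in enumerate(net.nodes)}
        for k, e in enumerate(net.edges):
            # flow defined positive a->b means P_a >= P_b
            sgn = np.sign(sol.edge_flow[k, 3])
            pa, pb = sol.node_pressure[idx[e.node_a], 3], sol.node_pressure[idx[e.node_b], 3]
            assert sgn * (pa - pb) >= -1e-12

    def test_viscosity_scaling_linearity(self):
        edges = [(0, 1, 100, 6), (1, 2, 80, 4), (1, 3, 90, 5)]
        t, q = inlet_waveform(T=4)
        p1 = build_flow_network(profile_from_edges(edges), mu=0.035, inlet_node=0)
        p2 = build_flow_network(profile_from_edges(edges), mu=0.070, inlet_node=0)
        s1, s2 = solve_network(p1, (t, q)), solve_network(p2, (t, q))
        assert np.allclose(s2.node_pressure, 2 * s1.node_pressure, rtol=1e-12)
        assert np.allclose(s2.edge_flow, s1.edge_flow, rtol=1e-12)

    def test_radius_fourth_power_law(self):
        e1 = build_flow_network(profile_from_edges([(0, 1, 100, 6)]),
                                inlet_node=0).edges[0]
        e2 = build_flow_network(profile_from_edges([(0, 1, 100, 3)]),
                                inlet_node=0).edges[0]
        assert e2.resistance == pytest.approx(16 * e1.resistance, rel=1e-9)


class TestFeatures:
    def _solution(self, T=32):
        p = profile_from_edges([(0, 1, 200, 6)])
        net = build_flow_network(p, inlet_node=0)
        return solve_network(net, inlet_waveform(T=T))

    def test_feature_count_formula_140(self):
        sol = self._solution(T=32)
        assert sol.n_faces == 2
        feats = extract_hemo_features(sol)
        F, T = 2, 32
        n_series_and_summaries = 2 * F * T + 6 * F
        assert n_series_and_summaries == 140
        # total = series + summaries + Qmax_Time + Qmax_Time_from_cm + Step_k
        assert len(feats) == n_series_and_summaries + 2 + T

    def test_qmax_time_is_waveform_argmax(self):
        sol = self._solution(T=21)
        feats = extract_hemo_features(sol)
        t, q = inlet_waveform(T=21)
        assert feats["Qmax_Time"] == pytest.approx(t[int(np.argmax(q))])
        assert feats["Qmax_Time_from_cm"] == feats["Qmax_Time"]
        assert feats["Step_10_mean"] == pytest.approx(sol.face_flow[:, 10].mean())

    def test_constant_waveform_tie_breaks_to_earliest(self):
        p = profile_from_edges([(0, 1, 200, 6)])
        net = build_flow_network(p, inlet_node=0)
        sol = solve_network(net, inlet_waveform(T=16, shape="constant"))
        feats = extract_hemo_features(sol)
        assert feats["Qmax_Time"] == 0.0

    def test_summaries_match_series(self):
        sol = self._solution()
        feats = extract_hemo_features(sol)
        assert feats["Q_face0_max"] == pytest.approx(sol.face_flow[0].max())
        assert feats["P_face1_min"] == pytest.approx(sol.face_pressure[1].min())
        assert feats["Q_face1_mean"] == pytest.approx(sol.face_flow[1].mean())

    def test_too_few_steps_rejected(self):
        sol = self._solution(T=10)
        with pytest.raises(ValueError, match="13"):
            extract_hemo_features(sol)
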