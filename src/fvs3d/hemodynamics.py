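"""Reduced-order pulsatile hemodynamics over the extracted vascular tree.

Each vessel segment becomes one edge of a lumped (0D) flow network with
Poiseuille resistance R = 8 mu L / (pi r^4).  A quasi-static solve at each
time step of the inlet waveform yields nodal pressures and edge flows from
linear mass-conservation equations; per-face (inlet/outlet cross-section)
flowrate and pressure time series plus their summaries form the feature
vector used for diagnosis: for F faces and T steps there are 2*F*T series
features and 6*F summary features (e.g. F=2, T=32 -> 140), plus the derived
Qmax_Time, Qmax_Time_from_cm and the per-step mean flowrates Step_k_mean.

Units are CGS internally (cm, s, dyn); blood viscosity default 0.035 dyn.s/cm2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ML_S_TO_L_MIN = 60.0 / 1000.0  # cm^3/s -> L/min


@dataclass
class FlowEdge:
    node_a: int
    node_b: int
    length: float       # cm
    radius: float       # cm
    resistance: float   # dyn.s/cm^5


@dataclass
class FlowNetwork:
    """Lumped vascular network: one inlet, one or more outlet nodes."""

    nodes: list[int]                   # node ids (from the vessel graph)
    edges: list[FlowEdge]
    inlet: int
    outlets: list[int]
    viscosity: float = 0.035
    outlet_pressure: float = 0.0       # gauge, dyn/cm^2

    @property
    def faces(self) -> list[int]:
        """Inlet first, then outlets — the cross-sections reported on."""
        return [self.inlet] + list(self.outlets)


@dataclass
class HemoSolution:
    network: FlowNetwork
    times: np.ndarray                  # (T,)
    face_flow: np.ndarray              # (F, T) cm^3/s, positive into the tree
    face_pressure: np.ndarray          # (F, T) dyn/cm^2
    node_pressure: np.ndarray          # (N, T)
    edge_flow: np.ndarray              # (E, T)

    @property
    def n_faces(self) -> int:
        return self.face_flow.shape[0]

    @property
    def n_steps(self) -> int:
        return self.face_flow.shape[1]


def poiseuille_resistance(length: float, radius: float, mu: float) -> float:
    return 8.0 * mu * length / (np.pi * radius ** 4)


def build_flow_network(profile_or_graph, mu: float = 0.035,
                       px_size: float | None = None,
                       inlet_node: int | None = None,
                       outlet_pressure: float = 0.0) -> FlowNetwork:
    """One edge per profiled segment: L = polyline length, r = median radius.

    ``px_size`` converts pixels to cm; when omitted it is taken from the
    profile (1.0 if absent there).  The inlet defaults to the endpoint
    node whose incident segment is widest (the root of the arterial tree);
    all other endpoint nodes become outlets.
    """
    if px_size is None:
        px_size = getattr(profile_or_graph, "px_size", 1.0)
    segs = profile_or_graph.segments
    node_ids: set[int] = set()
    edges: list[FlowEdge] = []
    degree: dict[int, int] = {}
    for s in segs:
        pts = np.asarray(s.points, dtype=float)
        L = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()) * px_size
        r = float(np.median(np.asarray(s.radii))) * px_size
        if L <= 0 or r <= 0:
            raise ValueError(f"segment {s.seg_id}: non-positive length or radius")
        edges.append(FlowEdge(s.node_a, s.node_b, L, r,
                              poiseuille_resistance(L, r, mu)))
        node_ids.update((s.node_a, s.node_b))
        for n in (s.node_a, s.node_b):
            degree[n] = degree.get(n, 0) + 1

    # connectivity check
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    g.add_edges_from((e.node_a, e.node_b) for e in edges)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        raise ValueError(f"flow network is disconnected: components {comps}")

    terminals = sorted(n for n, d in degree.items() if d == 1)
    if not terminals:
        raise ValueError("network has no terminal (endpoint) node for an inlet")
    if inlet_node is None:
        widest = {}
        for e in edges:
            for n in (e.node_a, e.node_b):
                if degree[n] == 1:
                    widest[n] = max(widest.get(n, 0.0), e.radius)
        inlet_node = max(widest, key=widest.get)
    outlets = [n for n in terminals if n != inlet_node]
    if not outlets:
        raise ValueError("network needs at least one outlet distinct from the inlet")
    return FlowNetwork(sorted(node_ids), edges, inlet_node, outlets,
                       viscosity=mu, outlet_pressure=outlet_pressure)


def inlet_waveform(T: int = 32, period: float = 1.0, peak_flow: float = 0.01,
                   shape: str = "half-sine", baseline_frac: float = 0.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Parametric inlet flow pulse sampled at T steps over one period.

    ``half-sine``: Q(t) = base + (peak-base) * sin(pi t / period), a single
    interior maximum at t = period/2.  ``constant``: Q(t) = peak.
    Returns (times, flows) in (s, cm^3/s).
    """
    if T < 2:
        raise ValueError("need at least 2 time steps")
    if peak_flow <= 0:
        raise ValueError("peak flow must be positive")
    t = np.linspace(0.0, period, T)
    if shape == "half-sine":
        base = baseline_frac * peak_flow
        q = base + (peak_flow - base) * np.sin(np.pi * t / period)
    elif shape == "constant":
        q = np.full(T, peak_flow)
    else:
        raise ValueError(f"unknown waveform shape: {shape}")
    return t, q


def solve_network(net: FlowNetwork, waveform: tuple[np.ndarray, np.ndarray]
                  ) -> HemoSolution:
    """Quasi-static nodal solve of Q = dP / R at every time step.

    Unknowns are the pressures at all non-outlet nodes; outlet nodes sit at
    the fixed boundary pressure.  Mass conservation at each free node with
    the prescribed inlet inflow closes the system.
    """
    times, qin = waveform
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    free = [n for n in nodes if n not in net.outlets]
    if not free or len(free) == len(nodes):
        raise ValueError("all outlets unconstrained: singular system")
    fidx = {n: i for i, n in enumerate(free)}

    A = np.zeros((len(free), len(free)))
    rhs_fixed = np.zeros(len(free))
    for e in net.edges:
        gcond = 1.0 / e.resistance
        for a, b in ((e.node_a, e.node_b), (e.node_b, e.node_a)):
            if a in fidx:
                A[fidx[a], fidx[a]] += gcond
                if b in fidx:
                    A[fidx[a], fidx[b]] -= gcond
                else:
                    rhs_fixed[fidx[a]] += gcond * net.outlet_pressure

    T = len(times)
    node_pressure = np.full((len(nodes), T), net.outlet_pressure)
    edge_flow = np.zeros((len(net.edges), T))
    inj = np.zeros(len(free))
    for t in range(T):
        inj[:] = 0.0
        inj[fidx[net.inlet]] = qin[t]
        p = np.linalg.solve(A, inj + rhs_fixed)
        for n, i in fidx.items():
            node_pressure[index[n], t] = p[i]
        for k, e in enumerate(net.edges):
            pa = node_pressure[index[e.node_a], t]
            pb = node_pressure[index[e.node_b], t]
            edge_flow[k, t] = (pa - pb) / e.resistance

    faces = net.faces
    face_flow = np.zeros((len(faces), T))
    face_pressure = np.zeros((len(faces), T))
    for fi, n in enumerate(faces):
        face_pressure[fi] = node_pressure[index[n]]
        for k, e in enumerate(net.edges):
            if e.node_a == n:
                face_flow[fi] += edge_flow[k]
            elif e.node_b == n:
                face_flow[fi] -= edge_flow[k]
    # report outlet flows as positive outflow magnitudes
    face_flow[1:] = -face_flow[1:]
    return HemoSolution(net, np.asarray(times), face_flow, face_pressure,
                        node_pressure, edge_flow)


def mass_conservation_residual(sol: HemoSolution) -> float:
    """Max relative net-flow imbalance over interior junction nodes and steps."""
    net = sol.network
    index = {n: i for i, n in enumerate(net.nodes)}
    terminals = set([net.inlet] + list(net.outlets))
    scale = max(np.abs(sol.edge_flow).max(), 1e-30)
    worst = 0.0
    for n in net.nodes:
        if n in terminals:
            continue
        bal = np.zeros(sol.n_steps)
        for k, e in enumerate(net.edges):
            if e.node_a == n:
                bal -= sol.edge_flow[k]
            elif e.node_b == n:
                bal += sol.edge_flow[k]
        worst = max(worst, float(np.abs(bal).max()) / scale)
    return worst


def extract_hemo_features(sol: HemoSolution) -> pd.Series:
    """Named feature vector in a fixed documented order.

    Order: Q_f0_t0..Q_f0_tT-1, ..., then P likewise per face; then per face
    Q_mean/Q_max/Q_min and P_mean/P_max/P_min; then Qmax_Time (time at which
    the across-face mean flowrate peaks; ties broken to the earliest step),
    Qmax_Time_from_cm (same statistic with flow in L/min), and Step_k_mean
    for every step k (across-face mean flowrate at step k).
    """
    F, T = sol.n_faces, sol.n_steps
    if T < 13:
        raise ValueError("need at least 13 steps so Step_12 exists")
    feats: dict[str, float] = {}
    for fi in range(F):
        for t in range(T):
            feats[f"Q_face{fi}_step{t}"] = float(sol.face_flow[fi, t])
        for t in range(T):
            feats[f"P_face{fi}_step{t}"] = float(sol.face_pressure[fi, t])
    for fi in range(F):
        q, p = sol.face_flow[fi], sol.face_pressure[fi]
        feats[f"Q_face{fi}_mean"] = float(q.mean())
        feats[f"Q_face{fi}_max"] = float(q.max())
        feats[f"Q_face{fi}_min"] = float(q.min())
        feats[f"P_face{fi}_mean"] = float(p.mean())
        feats[f"P_face{fi}_max"] = float(p.max())
        feats[f"P_face{fi}_min"] = float(p.min())

    mean_q = sol.face_flow.mean(axis=0)          # across faces, per step
    k_star = int(np.argmax(mean_q))              # earliest max by argmax rule
    feats["Qmax_Time"] = float(sol.times[k_star])
    mean_q_lmin = mean_q * ML_S_TO_L_MIN
    feats["Qmax_Time_from_cm"] = float(sol.times[int(np.argmax(mean_q_lmin))])
    for t in range(T):
        feats[f"Step_{t}_mean"] = float(mean_q[t])
    return pd.Series(feats)


def simulate_tree(profile_or_graph, mu: float = 0.035,
                  px_size: float | None = None,
                  T: int = 32, period: float = 1.0, peak_flow: float = 0.01,
                  inlet_node: int | None = None) -> tuple[HemoSolution, pd.Series]:
    """Convenience wrapper: network -> waveform -> solve -> features."""
    net = build_flow_network(profile_or_graph, mu=mu, px_size=px_size,
                             inlet_node=inlet_node)
    wf = inlet_waveform(T=T, period=period, peak_flow=peak_flow)
    sol = solve_network(net, wf)
    return sol, extract_hemo_features(sol)
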