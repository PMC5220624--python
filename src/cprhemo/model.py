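"""Pressure/flow evaluation and fixed-step integration of the closed loop.

The dynamical state is the 14-vector of compartment volumes.  Pressures
are recovered algebraically from volumes plus the instantaneous external
pressures (intrathoracic, mediastinal, gravitational), so volume is the
only integrated quantity and the loop conserves total blood volume to
rounding error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .forcing import (
    ForcingProtocol,
    compression_force,
    force_to_pressures,
    plr_pressure,
)
from .parameters import ModelParameters, NetworkArrays

__all__ = [
    "ModelState",
    "ForcingValues",
    "EdgeFlowSet",
    "SimulationTrace",
    "compute_pressures",
    "compute_flows",
    "derivatives",
    "integrate",
]


@dataclass(frozen=True)
class ModelState:
    """Instantaneous state: time and compartment volumes (L)."""

    t: float
    V: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "V", np.asarray(self.V, dtype=float))


@dataclass(frozen=True)
class ForcingValues:
    """External pressures applied at one instant (mmHg)."""

    p_lung: float = 0.0
    p_m: float = 0.0
    p_plr: float = 0.0


@dataclass(frozen=True)
class EdgeFlowSet:
    """Flows (L/s) on every directed edge, keyed by edge name."""

    names: tuple[str, ...]
    values: np.ndarray

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def _forcing_at(
    t: float, params: ModelParameters, protocol: ForcingProtocol
) -> tuple[float, ForcingValues]:
    force = compression_force(t, protocol.compression)
    p_lung, p_m = force_to_pressures(force, protocol.compression)
    p_plr = plr_pressure(t, protocol.plr, rho=params.rho, g=params.g)
    return force, ForcingValues(p_lung, p_m, p_plr)


def compute_pressures(
    state: ModelState,
    params: ModelParameters,
    forcing: ForcingValues = ForcingValues(),
    net: NetworkArrays | None = None,
) -> np.ndarray:
    """Compartment pressures (mmHg) at the state's instant.

    ``P_i = P0 + (V_i − V0_i)/C_i + lung_i·P_lung + m_i·P_M + plr_i·P_PLR``
    with the mediastinal coefficient ``m_i`` equal to 1 on the ventricles,
    f_tp on the remaining coupled chest compartments and 0 elsewhere.
    """
    net = net or params.network()
    V = np.asarray(state.V, dtype=float)
    if V.shape != net.V0.shape:
        raise ValueError(
            f"state has {V.size} volumes but the network has "
            f"{net.n_compartments} compartments"
        )
    return (
        net.P0
        + (V - net.V0) / net.C
        + net.lung * forcing.p_lung
        + net.med * forcing.p_m
        + net.plr * forcing.p_plr
    )


def compute_flows(
    pressures: np.ndarray,
    params: ModelParameters,
    compression_force: float = 0.0,
    net: NetworkArrays | None = None,
    gate_threshold: float = 1e-9,
) -> EdgeFlowSet:
    """Edge flows for a pressure vector and instantaneous sternal force.

    Resistive edges carry signed ΔP/R; valve edges are rectified to
    max(0, ΔP/R); the coronary edge carries zero whenever the force
    exceeds the gate threshold (compression phase).
    """
    net = net or params.network()
    P = np.asarray(pressures, dtype=float)
    if P.shape != net.V0.shape:
        raise ValueError("pressure vector length does not match the network")
    q = (P[net.edge_src] - P[net.edge_dst]) / net.edge_R
    valve = net.edge_valve.astype(bool)
    q[valve] = np.maximum(q[valve], 0.0)
    if compression_force > gate_threshold:
        q[net.edge_gated.astype(bool)] = 0.0
    return EdgeFlowSet(net.edge_names, q)


def derivatives(
    t: float,
    state: ModelState,
    params: ModelParameters,
    protocol: ForcingProtocol,
    net: NetworkArrays | None = None,
) -> np.ndarray:
    """dV/dt (L/s) per compartment: inflow minus outflow on every edge."""
    net = net or params.network()
    force, fv = _forcing_at(t, params, protocol)
    P = compute_pressures(state, params, fv, net=net)
    flows = compute_flows(
        P, params, force, net=net,
        gate_threshold=protocol.compression.force_gate_threshold,
    )
    dV = np.zeros(net.n_compartments)
    np.subtract.at(dV, net.edge_src, flows.values)
    np.add.at(dV, net.edge_dst, flows.values)
    return dV


@dataclass
class SimulationTrace:
    """Time-indexed record of one simulation run.

    With ``record_every > 1`` each recorded row is the block average of
    that many solver steps (anti-aliased decimation), so window means are
    insensitive to the recording rate even for fast transients such as
    the coronary inflow spike at the start of each restoring phase.
    """

    t: np.ndarray                 # (n,)
    V: np.ndarray                 # (n, 14) L
    P: np.ndarray                 # (n, 14) mmHg
    flows: np.ndarray             # (n, m) L/s
    force: np.ndarray             # (n,) N
    p_lung: np.ndarray            # (n,) mmHg
    p_m: np.ndarray               # (n,) mmHg
    p_plr: np.ndarray             # (n,) mmHg
    compartment_ids: tuple[str, ...]
    edge_names: tuple[str, ...]
    params: ModelParameters
    protocol: ForcingProtocol
    dt: float
    record_every: int = 1
    meta: dict = field(default_factory=dict)

    @property
    def sample_dt(self) -> float:
        return self.dt * self.record_every

    def volume(self, cid: str) -> np.ndarray:
        return self.V[:, self.compartment_ids.index(cid)]

    def pressure(self, cid: str) -> np.ndarray:
        return self.P[:, self.compartment_ids.index(cid)]

    def flow(self, name: str) -> np.ndarray:
        return self.flows[:, self.edge_names.index(name)]

    @property
    def total_volume(self) -> np.ndarray:
        return self.V.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"t": self.t}
        for j, cid in enumerate(self.compartment_ids):
            cols[f"V_{cid}"] = self.V[:, j]
        for j, cid in enumerate(self.compartment_ids):
            cols[f"P_{cid}"] = self.P[:, j]
        for j, name in enumerate(self.edge_names):
            cols[name] = self.flows[:, j]
        cols["force"] = self.force
        cols["P_lung"] = self.p_lung
        cols["P_M"] = self.p_m
        cols["P_PLR"] = self.p_plr
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["t"] = df["t"].map(lambda v: f"{v:.6f}")
        df.to_csv(path, index=False)


def _vector_force(t: np.ndarray, protocol: ForcingProtocol) -> np.ndarray:
    cfg = protocol.compression
    if cfg.amplitude == 0.0:
        return np.zeros_like(t)
    period = cfg.period
    tau = np.mod(t, period)
    t_comp = cfg.duty_cycle * period
    return np.where(
        tau < t_comp, cfg.amplitude * np.sin(np.pi * tau / t_comp), 0.0
    )


def _vector_plr(
    t: np.ndarray, protocol: ForcingProtocol, params: ModelParameters
) -> np.ndarray:
    plr = protocol.plr
    if plr is None:
        return np.zeros_like(t)
    full = plr_pressure(
        plr.start_time + plr.ramp + 1.0, plr, rho=params.rho, g=params.g
    )
    out = np.where(t >= plr.start_time, full, 0.0)
    if plr.ramp > 0.0:
        in_ramp = (t >= plr.start_time) & (t < plr.start_time + plr.ramp)
        out[in_ramp] = full * (t[in_ramp] - plr.start_time) / plr.ramp
    return out


def _block_decimate(arr: np.ndarray, k: int, dt: float | None = None):
    """Row 0 kept as-is; row j (j ≥ 1) is the mean of samples
    ``(j-1)k+1 .. jk``, labelled t = j·k·dt when ``dt`` is given."""
    n_blocks = (arr.shape[0] - 1) // k
    if dt is not None:
        return np.arange(n_blocks + 1) * k * dt
    body = arr[1:1 + n_blocks * k]
    body = body.reshape((n_blocks, k) + arr.shape[1:]).mean(axis=1)
    return np.concatenate([arr[:1], body], axis=0)


def integrate(
    params: ModelParameters,
    protocol: ForcingProtocol,
    dt: float = 1e-3,
    duration: float | None = None,
    record_every: int = 1,
    method: str = "rk4",
    V_init: np.ndarray | None = None,
) -> SimulationTrace:
    """Integrate the volume ODEs with fixed-step RK4 (or explicit Euler).

    ``duration`` defaults to the protocol duration.  Raises ``RuntimeError``
    naming the first compartment and time at which a non-finite volume
    appears.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if method not in ("rk4", "euler"):
        raise ValueError("method must be 'rk4' or 'euler'")
    duration = protocol.duration if duration is None else duration
    n_steps = int(round(duration / dt))
    net = params.network()
    V0 = net.V0 if V_init is None else np.asarray(V_init, dtype=float)

    cfg = protocol.compression
    plr = protocol.plr
    if plr is not None:
        p_plr_full = plr_pressure(
            plr.start_time + plr.ramp + 1.0, plr, rho=params.rho, g=params.g
        )
        plr_start, plr_ramp = plr.start_time, plr.ramp
    else:
        p_plr_full, plr_start, plr_ramp = 0.0, math.inf, 0.0

    V_rec, bad_step, bad_comp = _kernel.integrate_fixed_step(
        V0, dt, n_steps, 1, 1 if method == "euler" else 0,
        net.C, net.V0, net.lung, net.med, net.plr, net.P0,
        net.edge_src, net.edge_dst, net.edge_R, net.edge_valve,
        net.edge_gated,
        cfg.amplitude, cfg.period, cfg.duty_cycle, cfg.k_lung, cfg.k_med,
        cfg.force_gate_threshold,
        p_plr_full, plr_start, plr_ramp,
    )
    if bad_step >= 0:
        ids = params.ids if len(params.ids) > bad_comp else tuple(
            f"#{i}" for i in range(net.n_compartments)
        )
        raise RuntimeError(
            f"non-finite volume in compartment {ids[bad_comp]} at "
            f"t = {bad_step * dt:.4f} s"
        )

    t = np.arange(V_rec.shape[0]) * dt
    force = _vector_force(t, protocol)
    p_lung = cfg.k_lung * force
    p_m = cfg.k_med * force
    p_plr_arr = _vector_plr(t, protocol, params)

    P = (
        net.P0
        + (V_rec - net.V0) / net.C
        + np.outer(p_lung, net.lung)
        + np.outer(p_m, net.med)
        + np.outer(p_plr_arr, net.plr)
    )
    q = (P[:, net.edge_src] - P[:, net.edge_dst]) / net.edge_R
    valve = net.edge_valve.astype(bool)
    q[:, valve] = np.maximum(q[:, valve], 0.0)
    gated = net.edge_gated.astype(bool)
    q[np.ix_(force > cfg.force_gate_threshold, gated)] = 0.0

    if record_every > 1:
        k = record_every
        t, V_rec, P, q, force, p_lung, p_m, p_plr_arr = (
            _block_decimate(a, k, dt) if i == 0 else _block_decimate(a, k)
            for i, a in enumerate(
                (t, V_rec, P, q, force, p_lung, p_m, p_plr_arr)
            )
        )

    ids = params.ids
    return SimulationTrace(
        t=t, V=V_rec, P=P, flows=q, force=force, p_lung=p_lung, p_m=p_m,
        p_plr=p_plr_arr, compartment_ids=ids, edge_names=net.edge_names,
        params=params, protocol=protocol, dt=dt, record_every=record_every,
        meta={"method": method, "n_steps": n_steps},
    )
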