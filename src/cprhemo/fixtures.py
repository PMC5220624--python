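"""Miniature networks with known analytic behaviour, plus a short
default protocol.  Used as integrator oracles in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .forcing import ForcingProtocol, PlrConfig
from .parameters import Edge, ModelParameters, NetworkArrays

__all__ = ["make_fixture", "TwoCompartmentFixture", "LoopFixture",
           "ShortProtocolFixture", "run_network"]


def run_network(
    net: NetworkArrays,
    dt: float,
    duration: float,
    V_init: np.ndarray | None = None,
    method: str = "rk4",
    record_every: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate an arbitrary unforced network; returns (t, V)."""
    V0 = net.V0 if V_init is None else np.asarray(V_init, dtype=float)
    n_steps = int(round(duration / dt))
    V_rec, bad_step, bad_comp = _kernel.integrate_fixed_step(
        V0, dt, n_steps, record_every, 1 if method == "euler" else 0,
        net.C, net.V0, net.lung, net.med, net.plr, net.P0,
        net.edge_src, net.edge_dst, net.edge_R, net.edge_valve,
        net.edge_gated,
        0.0, 1.0, 0.5, 0.0, 0.0, 1e-9,   # zero compression
        0.0, math.inf, 0.0,               # no PLR
    )
    if bad_step >= 0:
        raise RuntimeError(
            f"non-finite volume in compartment #{bad_comp} at "
            f"t = {bad_step * dt:.4f} s"
        )
    t = np.arange(V_rec.shape[0]) * dt * record_every
    return t, V_rec


@dataclass(frozen=True)
class TwoCompartmentFixture:
    """Two equal RC compartments exchanging volume through one resistance.

    A volume excess δ placed on one side decays as exp(−t/τ) with
    τ = R·C1·C2/(C1 + C2) — the closed-form oracle for the integrator.
    """

    R: float = 100.0
    C1: float = 0.01
    C2: float = 0.01
    V0_each: float = 0.5

    @property
    def tau(self) -> float:
        return self.R * self.C1 * self.C2 / (self.C1 + self.C2)

    def network(self) -> NetworkArrays:
        return NetworkArrays.from_edges(
            C=[self.C1, self.C2], V0=[self.V0_each, self.V0_each],
            edges=[Edge("q_link", 0, 1, self.R)],
        )

    def run(
        self, delta: float = 0.05, dt: float = 1e-3, duration: float = 3.0,
        method: str = "rk4",
    ) -> tuple[np.ndarray, np.ndarray]:
        """Integrate from a state with +δ on side 0 and −δ on side 1."""
        V_init = np.array([self.V0_each + delta, self.V0_each - delta])
        return run_network(self.network(), dt, duration, V_init, method)

    def analytic_excess(self, t: np.ndarray, delta: float = 0.05) -> np.ndarray:
        """Exact volume excess of compartment 0 at times ``t``."""
        return delta * np.exp(-np.asarray(t) / self.tau)


@dataclass(frozen=True)
class LoopFixture:
    """Three compartments in a resistive ring with no valves.

    At uniform pressure every gradient vanishes, so the dynamics are
    identically zero.
    """

    R: float = 50.0
    C: float = 0.02
    V0_each: float = 0.4

    def network(self) -> NetworkArrays:
        edges = [
            Edge("q_01", 0, 1, self.R),
            Edge("q_12", 1, 2, self.R),
            Edge("q_20", 2, 0, self.R),
        ]
        return NetworkArrays.from_edges(
            C=[self.C] * 3, V0=[self.V0_each] * 3, edges=edges,
        )

    def run(self, dt: float = 1e-3, duration: float = 1.0):
        return run_network(self.network(), dt, duration)


@dataclass(frozen=True)
class ShortProtocolFixture:
    """Default subject with a 12 s compression-only protocol (no PLR)."""

    params: ModelParameters
    protocol: ForcingProtocol


def make_fixture(kind: str):
    """Return a named fixture bundle.

    ``kind`` is one of ``two-compartment-loop``, ``no-valves-loop``,
    ``paper-default-short``.
    """
    if kind == "two-compartment-loop":
        return TwoCompartmentFixture()
    if kind == "no-valves-loop":
        return LoopFixture()
    if kind == "paper-default-short":
        return ShortProtocolFixture(
            params=ModelParameters(),
            protocol=ForcingProtocol(plr=None, duration=12.0),
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
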