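"""Compartment table, peripheral resistances and network topology.

The circulation is a closed loop of 14 lumped compartments (four heart
chambers, pulmonary circulation, thoracic aorta, head/neck, abdomen and
legs).  Each compartment is a capacitance fed/drained through resistances;
heart valves and the two venous return valves are ideal diodes.  External
pressures (intrathoracic, mediastinal, gravitational) couple into subsets
of compartments selected by per-compartment flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "CompartmentSpec",
    "PeripheralResistances",
    "Edge",
    "ModelParameters",
    "NetworkArrays",
    "build_default_parameters",
    "MMHG_PER_PA",
    "TOTAL_BLOOD_VOLUME_L",
]

#: 1 mmHg expressed in pascal.
PA_PER_MMHG = 133.322
MMHG_PER_PA = 1.0 / PA_PER_MMHG

#: Whole blood volume of the default subject (L).
TOTAL_BLOOD_VOLUME_L = 4.36

_REGIONS = ("chest", "head", "abdomen", "legs")
_MED_MODES = ("full", "tpf_scaled", "none")


@dataclass(frozen=True)
class CompartmentSpec:
    """One lumped vascular segment.

    Parameters
    ----------
    id : str
        Compartment label ``C1`` .. ``C14``.
    name : str
        Anatomical description.
    R_out : float
        Outflow resistance (mmHg·s/L) as printed in the parameter table;
        a printed 0 is replaced by ``ModelParameters.epsilon_R`` when the
        flow network is assembled.
    C : float
        Capacitance (L/mmHg).
    V0 : float
        Initial (cardiac-arrest equilibrium) volume, L.
    valve_out : bool
        Outflow passes a one-way valve (diode).
    region : str
        ``chest`` | ``head`` | ``abdomen`` | ``legs``.
    lung_coupling : int
        1 if the compartment feels the intrathoracic pressure P_lung
        (all chest compartments), else 0.
    mediastinal_mode : str
        ``full`` — receives the mediastinal pressure P_M unscaled (the
        two ventricles); ``tpf_scaled`` — receives f_tp·P_M (remaining
        chest compartments except those buried in the lungs);
        ``none`` — no mediastinal coupling.
    """

    id: str
    name: str
    R_out: float
    C: float
    V0: float
    valve_out: bool = False
    region: str = "chest"
    lung_coupling: int = 0
    mediastinal_mode: str = "none"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"{self.id}: capacitance must be > 0")
        if self.V0 <= 0:
            raise ValueError(f"{self.id}: initial volume must be > 0")
        if self.R_out < 0:
            raise ValueError(f"{self.id}: resistance must be >= 0")
        if self.region not in _REGIONS:
            raise ValueError(f"{self.id}: unknown region {self.region!r}")
        if self.mediastinal_mode not in _MED_MODES:
            raise ValueError(
                f"{self.id}: unknown mediastinal_mode {self.mediastinal_mode!r}"
            )


@dataclass(frozen=True)
class PeripheralResistances:
    """Peripheral vascular-bed resistances (mmHg·s/L).

    ``Rht`` (coronary) is phase-gated: during the compression phase the
    coronary bed is treated as infinite (no flow); during the restoring
    phase it takes this finite value.
    """

    Rh: float = 5520.0    # head and neck
    Rht: float = 10780.0  # coronary, restoring phase only
    Rs: float = 1800.0    # splanchnic
    Rl: float = 8520.0    # legs
    Rpc: float = 105.0    # pulmonary capillary bed

    def __post_init__(self) -> None:
        for key in ("Rh", "Rht", "Rs", "Rl", "Rpc"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be strictly positive")


@dataclass(frozen=True)
class Edge:
    """A directed flow path ``src -> dst`` through resistance ``R``."""

    name: str
    src: int          # 0-based compartment index
    dst: int
    R: float          # mmHg·s/L
    valve: bool = False
    gated: bool = False  # coronary: blocked while compression force > 0


def _default_compartments() -> tuple[CompartmentSpec, ...]:
    # id, name, R_out, C, V0, valve_out, region, med_mode
    rows = [
        ("C1", "Right atrium and intrathoracic great veins",
         0.0, 0.00950, 0.367, True, "chest", "tpf_scaled"),
        ("C2", "Right ventricle", 5.0, 0.016, 0.150, True, "chest", "full"),
        ("C3", "Large pulmonary arteries", 10.0, 0.0042, 0.109, False, "chest",
         "tpf_scaled"),
        ("C4", "Peripheral pulmonary arteries", 10.0, 0.00042, 0.160, False,
         "chest", "none"),
        ("C5", "Peripheral pulmonary veins", 5.0, 0.00128, 0.300, False,
         "chest", "none"),
        ("C6", "Central pulmonary veins and left atrium",
         0.0, 0.0128, 0.250, True, "chest", "tpf_scaled"),
        ("C7", "Left ventricle", 5.0, 0.0080, 0.150, True, "chest", "full"),
        ("C8", "Thoracic aorta", 10.0, 0.00080, 0.078, False, "chest",
         "tpf_scaled"),
        ("C9", "Carotid arteries", 60.0, 0.00020, 0.132, False, "head", "none"),
        ("C10", "Jugular veins", 30.0, 0.01200, 0.216, True, "head", "none"),
        ("C11", "Abdominal aorta", 25.0, 0.00040, 0.114, False, "abdomen",
         "none"),
        ("C12", "Femoral arteries", 360.0, 0.00020, 0.133, False, "legs",
         "none"),
        ("C13", "Femoral veins", 180.0, 0.00470, 0.267, True, "legs", "none"),
        ("C14", "Inferior vena cava", 25.0, 0.02340, 1.930, False, "abdomen",
         "none"),
    ]
    return tuple(
        CompartmentSpec(
            id=cid, name=name, R_out=r, C=c, V0=v0, valve_out=valve,
            region=region, lung_coupling=1 if region == "chest" else 0,
            mediastinal_mode=med,
        )
        for cid, name, r, c, v0, valve, region, med in rows
    )


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the closed-loop model.

    ``tpf`` is the thoracic pump factor f_tp in [0, 1]: the weight with
    which the mediastinal compression pressure reaches the non-ventricular
    chest compartments (0 = pure cardiac pump, 1 = pure thoracic pump).
    """

    compartments: tuple[CompartmentSpec, ...] = field(
        default_factory=_default_compartments
    )
    peripherals: PeripheralResistances = field(
        default_factory=PeripheralResistances
    )
    tpf: float = 0.75
    rho: float = 1060.0        # blood density, kg/m^3
    g: float = 9.8             # gravitational acceleration, N/kg
    leg_length: float = 0.79   # m (45% of a 175 cm subject)
    epsilon_R: float = 1.0     # substitute for printed R = 0, mmHg·s/L
    P0: float = 7.0            # uniform arrest (mean circulatory filling)
    #                            pressure, mmHg

    def __post_init__(self) -> None:
        if not 0.0 <= self.tpf <= 1.0:
            raise ValueError("tpf must lie in [0, 1]")
        if len(self.compartments) != 14:
            raise ValueError("the closed loop has exactly 14 compartments")
        if self.epsilon_R <= 0:
            raise ValueError("epsilon_R must be > 0")
        total = sum(c.V0 for c in self.compartments)
        if abs(total - TOTAL_BLOOD_VOLUME_L) > 0.005:
            raise ValueError(
                f"total initial volume {total:.4f} L differs from "
                f"{TOTAL_BLOOD_VOLUME_L} L by more than 0.005 L"
            )

    # -- convenience -----------------------------------------------------
    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.compartments)

    def index(self, cid: str) -> int:
        return self.ids.index(cid)

    @property
    def V0(self) -> np.ndarray:
        return np.array([c.V0 for c in self.compartments])

    def with_tpf(self, tpf: float) -> "ModelParameters":
        return replace(self, tpf=tpf)

    def _r_out(self, i: int) -> float:
        r = self.compartments[i].R_out
        return self.epsilon_R if r == 0.0 else r

    def edges(self) -> tuple[Edge, ...]:
        """Assemble the directed flow network.

        Inter-compartment flow uses the upstream compartment's outflow
        resistance, except the femoral inflow C11→C12 which the governing
        equations put through the femoral arterial resistance R_C12, and
        the peripheral beds which use Rh/Rl/Rs/Rpc/Rht.  The coronary path
        runs thoracic aorta → right atrium through Rht and is blocked
        whenever the compression force is positive.
        """
        p = self.peripherals
        r = self._r_out
        e = [
            Edge("q_tricuspid", 0, 1, r(0), valve=True),
            Edge("q_pulmonary_valve", 1, 2, r(1), valve=True),
            Edge("q_pulm_art", 2, 3, r(2)),
            Edge("q_pulm_cap", 3, 4, p.Rpc),
            Edge("q_pulm_vein", 4, 5, r(4)),
            Edge("q_mitral", 5, 6, r(5), valve=True),
            Edge("q_aortic_valve", 6, 7, r(6), valve=True),
            Edge("q_carotid_in", 7, 8, r(7)),
            Edge("q_head", 8, 9, p.Rh),
            Edge("q_jugular_return", 9, 0, r(9), valve=True),
            Edge("q_abdominal_in", 7, 10, r(7)),
            Edge("q_femoral_in", 10, 11, r(11)),
            Edge("q_leg_bed", 11, 12, p.Rl),
            Edge("q_femoral_return", 12, 13, r(12), valve=True),
            Edge("q_splanchnic", 10, 13, p.Rs),
            Edge("q_ivc_return", 13, 0, r(13)),
            Edge("q_coronary", 7, 0, p.Rht, valve=True, gated=True),
        ]
        return tuple(e)

    def network(self) -> "NetworkArrays":
        return NetworkArrays.from_parameters(self)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "compartments": [
                {
                    "id": c.id, "name": c.name, "R_out": c.R_out, "C": c.C,
                    "V0": c.V0, "valve_out": c.valve_out, "region": c.region,
                    "lung_coupling": c.lung_coupling,
                    "mediastinal_mode": c.mediastinal_mode,
                }
                for c in self.compartments
            ],
            "peripherals": {
                k: getattr(self.peripherals, k)
                for k in ("Rh", "Rht", "Rs", "Rl", "Rpc")
            },
            "tpf": self.tpf,
            "rho": self.rho,
            "g": self.g,
            "leg_length": self.leg_length,
            "epsilon_R": self.epsilon_R,
            "P0": self.P0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        comps = tuple(
            CompartmentSpec(**row) for row in d.get("compartments", [])
        ) or _default_compartments()
        per = PeripheralResistances(**d.get("peripherals", {}))
        scalars = {
            k: d[k]
            for k in ("tpf", "rho", "g", "leg_length", "epsilon_R", "P0")
            if k in d
        }
        return cls(compartments=comps, peripherals=per, **scalars)


@dataclass(frozen=True)
class NetworkArrays:
    """Flat ndarray view of the network consumed by the integrator kernel."""

    C: np.ndarray          # (n,) capacitances
    V0: np.ndarray         # (n,) reference volumes
    lung: np.ndarray       # (n,) 0/1 intrathoracic coupling
    med: np.ndarray        # (n,) mediastinal coefficient: 1, f_tp or 0
    plr: np.ndarray        # (n,) 0/1 gravitational (leg) coupling
    P0: float
    edge_src: np.ndarray   # (m,) int64
    edge_dst: np.ndarray   # (m,) int64
    edge_R: np.ndarray     # (m,) float
    edge_valve: np.ndarray  # (m,) uint8
    edge_gated: np.ndarray  # (m,) uint8
    edge_names: tuple[str, ...]

    @classmethod
    def from_parameters(cls, params: ModelParameters) -> "NetworkArrays":
        comps = params.compartments
        med_coeff = {"full": 1.0, "tpf_scaled": params.tpf, "none": 0.0}
        edges = params.edges()
        return cls(
            C=np.array([c.C for c in comps]),
            V0=np.array([c.V0 for c in comps]),
            lung=np.array([float(c.lung_coupling) for c in comps]),
            med=np.array([med_coeff[c.mediastinal_mode] for c in comps]),
            plr=np.array(
                [1.0 if c.region == "legs" else 0.0 for c in comps]
            ),
            P0=params.P0,
            edge_src=np.array([e.src for e in edges], dtype=np.int64),
            edge_dst=np.array([e.dst for e in edges], dtype=np.int64),
            edge_R=np.array([e.R for e in edges]),
            edge_valve=np.array([e.valve for e in edges], dtype=np.uint8),
            edge_gated=np.array([e.gated for e in edges], dtype=np.uint8),
            edge_names=tuple(e.name for e in edges),
        )

    @classmethod
    def from_edges(
        cls,
        C: Iterable[float],
        V0: Iterable[float],
        edges: Iterable[Edge],
        P0: float = 0.0,
        lung: Iterable[float] | None = None,
        med: Iterable[float] | None = None,
        plr: Iterable[float] | None = None,
    ) -> "NetworkArrays":
        """Build an arbitrary small network (used by test fixtures)."""
        C = np.asarray(list(C), dtype=float)
        V0 = np.asarray(list(V0), dtype=float)
        n = C.size
        edges = list(edges)
        zeros = np.zeros(n)
        return cls(
            C=C, V0=V0,
            lung=np.asarray(list(lung), dtype=float) if lung is not None else zeros.copy(),
            med=np.asarray(list(med), dtype=float) if med is not None else zeros.copy(),
            plr=np.asarray(list(plr), dtype=float) if plr is not None else zeros.copy(),
            P0=P0,
            edge_src=np.array([e.src for e in edges], dtype=np.int64),
            edge_dst=np.array([e.dst for e in edges], dtype=np.int64),
            edge_R=np.array([e.R for e in edges], dtype=float),
            edge_valve=np.array([e.valve for e in edges], dtype=np.uint8),
            edge_gated=np.array([e.gated for e in edges], dtype=np.uint8),
            edge_names=tuple(e.name for e in edges),
        )

    @property
    def n_compartments(self) -> int:
        return self.C.size

    @property
    def n_edges(self) -> int:
        return self.edge_R.size


def build_default_parameters(**overrides) -> ModelParameters:
    """Parameters of the average adult subject (175 cm, 70 kg, 4.36 L blood).

    Keyword overrides are applied on top of the defaults, e.g.
    ``build_default_parameters(tpf=0.5)``.
    """
    return ModelParameters(**overrides)
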