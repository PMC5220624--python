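"""Scripted experiments: TPF sweep, angle sweep, oedema grid, summary
table, and the PETCO2↔CO linear bridge.

Every experiment is deterministic: re-running with the same configuration
reproduces the same CSV bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .forcing import ForcingProtocol, PlrConfig
from .metrics import (
    ComparisonResult,
    compare_plr,
    edema_check,
    leg_volume_transfer,
)
from .model import integrate
from .parameters import ModelParameters, build_default_parameters

__all__ = [
    "SweepResult",
    "tpf_sweep",
    "angle_sweep",
    "edema_grid",
    "petco2_change_from_co",
    "co_change_from_petco2",
    "reproduce_table3",
    "TABLE3_REFERENCE",
]

#: Published working-point values the summary table is compared against:
#: (CO L/min, Q_heart mL/s, Q_head mL/s) before PLR, after PLR (90°), and
#: percent increase, per thoracic pump factor.
TABLE3_REFERENCE = {
    0.0: {"co": (2.0, 2.2, 10.0), "q_heart": (1.9, 2.1, 10.0),
          "q_head": (6.9, 7.6, 10.0)},
    0.5: {"co": (1.5, 1.7, 15.0), "q_heart": (1.4, 1.6, 17.0),
          "q_head": (5.8, 6.6, 14.0)},
    1.0: {"co": (1.1, 1.1, 0.0), "q_heart": (0.8, 0.8, 0.0),
          "q_head": (4.8, 5.2, 9.0)},
}


@dataclass(frozen=True)
class SweepResult:
    """One comparison per point of a strictly increasing parameter axis."""

    axis_name: str
    axis: tuple[float, ...]
    results: tuple[ComparisonResult, ...]

    def __post_init__(self) -> None:
        if list(self.axis) != sorted(set(self.axis)):
            raise ValueError(f"{self.axis_name} axis must be strictly increasing")
        if len(self.axis) != len(self.results):
            raise ValueError("one result required per axis point")

    def pct_change(self, metric: str) -> np.ndarray:
        return np.array([r.pct_change[metric] for r in self.results])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for x, r in zip(self.axis, self.results):
            transferred, fraction = leg_volume_transfer(r)
            row = {self.axis_name: x}
            for m in ("cpp", "co", "q_heart", "q_head"):
                row[f"{m}_before"] = getattr(r.before, m)
                row[f"{m}_after"] = getattr(r.after, m)
                row[f"{m}_change_pct"] = r.pct_change[m]
            row["v_legs_before"] = r.before.v_legs
            row["v_legs_after"] = r.after.v_legs
            row["transferred_ml"] = transferred
            row["transferred_fraction_pct"] = fraction
            rows.append(row)
        return pd.DataFrame(rows)


def _run_point(
    params: ModelParameters,
    protocol: ForcingProtocol,
    tpf: float,
    angle: float,
    keep_trace: bool = False,
) -> ComparisonResult:
    p = params.with_tpf(tpf)
    plr = protocol.plr or PlrConfig()
    proto = replace(protocol, plr=replace(plr, angle_deg=angle))
    res = compare_plr(p, proto)
    if not keep_trace:
        res = replace(res, trace=None)
    return res


def tpf_sweep(
    tpfs,
    angle: float = 90.0,
    params: ModelParameters | None = None,
    protocol: ForcingProtocol | None = None,
) -> SweepResult:
    """PLR comparison across thoracic pump factors at a fixed angle."""
    params = params or build_default_parameters()
    protocol = protocol or ForcingProtocol(plr=PlrConfig(angle_deg=angle))
    tpfs = tuple(float(x) for x in tpfs)
    if any(not 0.0 <= x <= 1.0 for x in tpfs):
        raise ValueError("tpf values must lie in [0, 1]")
    results = tuple(_run_point(params, protocol, x, angle) for x in tpfs)
    return SweepResult("tpf", tpfs, results)


def angle_sweep(
    angles,
    tpf: float = 0.75,
    params: ModelParameters | None = None,
    protocol: ForcingProtocol | None = None,
) -> SweepResult:
    """PLR comparison across leg-elevation angles at a fixed pump factor."""
    params = params or build_default_parameters()
    protocol = protocol or ForcingProtocol(plr=PlrConfig())
    angles = tuple(float(a) for a in angles)
    if any(not 0.0 <= a <= 90.0 for a in angles):
        raise ValueError("angles must lie in [0°, 90°]")
    results = tuple(_run_point(params, protocol, tpf, a) for a in angles)
    return SweepResult("angle_deg", angles, results)


def edema_grid(
    tpfs=(0.0, 0.25, 0.5, 0.75, 1.0),
    angles=(0.0, 30.0, 45.0, 60.0, 90.0),
    params: ModelParameters | None = None,
    protocol: ForcingProtocol | None = None,
    window: tuple[float, float] = (30.0, 40.0),
    threshold: float = 25.0,
) -> pd.DataFrame:
    """Mean peripheral pulmonary venous pressure over the (TPF, angle) grid.

    Returns a tidy frame with columns tpf, angle_deg, p_ppv_mean, safe;
    the post-PLR window is used so the gravitational load is included.
    """
    params = params or build_default_parameters()
    protocol = protocol or ForcingProtocol(plr=PlrConfig())
    rows = []
    for tpf in tpfs:
        p = params.with_tpf(float(tpf))
        for angle in angles:
            plr = replace(protocol.plr or PlrConfig(), angle_deg=float(angle))
            proto = replace(protocol, plr=plr)
            trace = integrate(p, proto)
            chk = edema_check(trace, window, threshold=threshold)
            rows.append({
                "tpf": float(tpf), "angle_deg": float(angle),
                "p_ppv_mean": chk.p_ppv_mean, "safe": chk.safe,
            })
    return pd.DataFrame(rows)


def petco2_change_from_co(co_change_pct: float) -> float:
    """PETCO2 percent change predicted from a CO percent change.

    Linear bridge ``y = 0.33·x + 0.13`` between percent changes in
    cardiac output (x) and end-tidal CO2 (y); stated for decreases and
    applied with the same slope and intercept to increases.
    """
    return 0.33 * co_change_pct + 0.13


def co_change_from_petco2(petco2_change_pct: float) -> float:
    """Inverse of :func:`petco2_change_from_co`."""
    return (petco2_change_pct - 0.13) / 0.33


def reproduce_table3(
    params: ModelParameters | None = None,
    protocol: ForcingProtocol | None = None,
    tpfs=(0.0, 0.5, 1.0),
) -> pd.DataFrame:
    """Before/after/percent summary at TPF 0, 0.5, 1 with PLR at 90°.

    Simulated CO (L/min) and coronary/head flows (mL/s) are reported next
    to the published working-point values with absolute deviations; the
    deviations are reported, not asserted.
    """
    sweep = tpf_sweep(tpfs, angle=90.0, params=params, protocol=protocol)
    rows = []
    for tpf, res in zip(sweep.axis, sweep.results):
        ref = TABLE3_REFERENCE.get(tpf)
        for metric in ("co", "q_heart", "q_head"):
            row = {
                "tpf": tpf, "metric": metric,
                "before": getattr(res.before, metric),
                "after": getattr(res.after, metric),
                "change_pct": res.pct_change[metric],
            }
            if ref is not None:
                rb, ra, rp = ref[metric]
                row.update({
                    "ref_before": rb, "ref_after": ra, "ref_change_pct": rp,
                    "dev_before": row["before"] - rb,
                    "dev_after": row["after"] - ra,
                    "dev_change_pct": row["change_pct"] - rp,
                })
            rows.append(row)
    return pd.DataFrame(rows)
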