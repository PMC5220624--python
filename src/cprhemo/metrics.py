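"""Windowed summary metrics and before/after-PLR comparisons.

Cardiac output is the time-mean aortic-valve flow; Q_heart and Q_head are
the mean coronary and head-bed flows; coronary perfusion pressure (CPP)
is the restoring-phase mean of aortic minus right-atrial pressure, the
standard CPR definition.  Means are taken over a whole number of
compression cycles so that the phase of the window boundaries does not
bias them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcing import ForcingProtocol
from .model import SimulationTrace, integrate
from .parameters import ModelParameters

__all__ = [
    "SummaryMetrics",
    "ComparisonResult",
    "EdemaCheck",
    "summarize",
    "compare_plr",
    "leg_volume_transfer",
    "edema_check",
    "PCT_METRICS",
]

#: Metrics for which percent changes are reported.
PCT_METRICS = ("co", "cpp", "q_heart", "q_head", "v_legs", "v_abdomen",
               "p_ppv_mean")


@dataclass(frozen=True)
class SummaryMetrics:
    """Cycle-averaged quantities over one measurement window."""

    co: float          # cardiac output, L/min
    cpp: float         # coronary perfusion pressure, mmHg
    q_heart: float     # coronary flow, mL/s
    q_head: float      # head-bed flow, mL/s
    v_legs: float      # femoral arterial + venous volume, mL
    v_abdomen: float   # abdominal aorta + inferior vena cava volume, mL
    p_ppv_mean: float  # peripheral pulmonary venous pressure, mmHg
    window: tuple[float, float]

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PCT_METRICS}


@dataclass(frozen=True)
class ComparisonResult:
    """Before/after-PLR summary pair with percent changes.

    ``pct_change[m] = (after − before)/before × 100``; NaN (and membership
    in ``undefined``) when the before value is zero.
    """

    before: SummaryMetrics
    after: SummaryMetrics
    pct_change: dict[str, float]
    undefined: frozenset[str] = frozenset()
    trace: SimulationTrace | None = None


@dataclass(frozen=True)
class EdemaCheck:
    """Mean peripheral pulmonary venous pressure vs the oncotic threshold."""

    p_ppv_mean: float
    threshold: float
    safe: bool


def _window_mask(
    trace: SimulationTrace, window: tuple[float, float]
) -> tuple[np.ndarray, tuple[float, float]]:
    a, b = window
    if b > trace.t[-1] + 1e-9:
        raise ValueError(
            f"window end {b} s exceeds trace end {trace.t[-1]:.3f} s"
        )
    period = trace.protocol.compression.period
    n_cyc = int(np.floor((b - a) / period + 1e-9))
    if n_cyc < 1:
        raise ValueError(
            f"window ({a}, {b}) s is shorter than one compression cycle "
            f"({period} s)"
        )
    b_eff = a + n_cyc * period
    mask = (trace.t >= a - 1e-12) & (trace.t < b_eff - 1e-12)
    return mask, (a, b_eff)


def summarize(
    trace: SimulationTrace, window: tuple[float, float]
) -> SummaryMetrics:
    """Reduce a trace to the summary quantities over ``window``.

    The window is truncated to the largest whole number of compression
    cycles that fits; CPP is averaged over the restoring-phase samples
    only (zero sternal force).
    """
    mask, eff = _window_mask(trace, window)
    gate = trace.protocol.compression.force_gate_threshold
    restoring = mask & (trace.force <= gate)

    co = float(trace.flow("q_aortic_valve")[mask].mean() * 60.0)
    q_heart = float(trace.flow("q_coronary")[mask].mean() * 1000.0)
    q_head = float(trace.flow("q_head")[mask].mean() * 1000.0)
    dp = trace.pressure("C8") - trace.pressure("C1")
    cpp = float(dp[restoring].mean()) if restoring.any() else 0.0
    v_legs = float(
        (trace.volume("C12") + trace.volume("C13"))[mask].mean() * 1000.0
    )
    v_abdomen = float(
        (trace.volume("C11") + trace.volume("C14"))[mask].mean() * 1000.0
    )
    p_ppv = float(trace.pressure("C5")[mask].mean())
    return SummaryMetrics(
        co=co, cpp=cpp, q_heart=q_heart, q_head=q_head, v_legs=v_legs,
        v_abdomen=v_abdomen, p_ppv_mean=p_ppv, window=eff,
    )


def compare_windows(
    trace: SimulationTrace,
    before_window: tuple[float, float] = (10.0, 20.0),
    after_window: tuple[float, float] = (30.0, 40.0),
    keep_trace: bool = True,
) -> ComparisonResult:
    """Summarize two windows of an existing trace and take percent changes."""
    before = summarize(trace, before_window)
    after = summarize(trace, after_window)
    pct: dict[str, float] = {}
    undefined = set()
    for m in PCT_METRICS:
        b = getattr(before, m)
        a = getattr(after, m)
        if b == 0.0:
            pct[m] = float("nan")
            undefined.add(m)
        else:
            pct[m] = (a - b) / b * 100.0
    return ComparisonResult(
        before=before, after=after, pct_change=pct,
        undefined=frozenset(undefined),
        trace=trace if keep_trace else None,
    )


def compare_plr(
    params: ModelParameters,
    protocol: ForcingProtocol,
    before_window: tuple[float, float] = (10.0, 20.0),
    after_window: tuple[float, float] = (30.0, 40.0),
    dt: float = 1e-3,
    record_every: int = 1,
) -> ComparisonResult:
    """Run the protocol once and compare pre-PLR vs post-PLR windows.

    The protocol must extend past the after-window and (if PLR is
    configured) start the manoeuvre between the two windows.
    """
    if protocol.duration < after_window[1]:
        raise ValueError(
            "protocol duration must cover the post-PLR window "
            f"(needs ≥ {after_window[1]} s, got {protocol.duration} s)"
        )
    trace = integrate(
        params, protocol, dt=dt, duration=protocol.duration,
        record_every=record_every,
    )
    return compare_windows(trace, before_window, after_window)


def leg_volume_transfer(result: ComparisonResult) -> tuple[float, float]:
    """Volume moved out of the legs by PLR.

    Returns ``(transferred_ml, fraction_pct)`` where the fraction is
    relative to the pre-PLR leg volume.
    """
    before = result.before.v_legs
    if before == 0.0:
        raise ValueError("pre-PLR leg volume is zero; fraction undefined")
    transferred = before - result.after.v_legs
    return transferred, transferred / before * 100.0


def edema_check(
    trace: SimulationTrace,
    window: tuple[float, float],
    threshold: float = 25.0,
) -> EdemaCheck:
    """Pulmonary-oedema safety flag.

    The peripheral pulmonary venous pressure approximates pulmonary
    capillary pressure; staying below the plasma colloid osmotic pressure
    (25–30 mmHg; the conservative 25 mmHg end is the default threshold)
    is taken as oedema-safe.
    """
    p = summarize(trace, window).p_ppv_mean
    return EdemaCheck(p_ppv_mean=p, threshold=threshold, safe=p < threshold)
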