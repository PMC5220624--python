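"""Chest-compression forcing and passive-leg-raising (PLR) gravity pressure.

Compressions are non-overlapping half-sinusoids (default 400 N amplitude,
100 min^-1, 50% duty cycle).  The sternal force is mapped linearly to an
intrathoracic pressure P_lung (felt by every chest compartment) and a
mediastinal pressure P_M (felt by the ventricles, and by the remaining
chest compartments scaled by the thoracic pump factor).  The two linear
coefficients are not independently observable; they are tied by a fixed
ratio and their common scale is calibrated once so that steady-state
cardiac output during compression-only CPR at TPF 0.75 matches the
1.30 L/min working point (see :func:`calibrate_force_coupling`).

Raising the legs by an angle α adds the hydrostatic pressure of the
mid-column of leg blood, ρ·g·(l/2)·sin α, to the femoral arterial and
venous compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .parameters import MMHG_PER_PA, ModelParameters

__all__ = [
    "CompressionConfig",
    "PlrConfig",
    "ForcingProtocol",
    "compression_force",
    "force_to_pressures",
    "plr_pressure",
    "calibrate_force_coupling",
    "DEFAULT_K_LUNG",
    "DEFAULT_K_MED",
]

#: Calibrated force→pressure coefficients (mmHg per N), frozen from
#: ``calibrate_force_coupling`` on the default model (TPF 0.75, no PLR,
#: target cardiac output 1.30 L/min, k_med/k_lung ratio 1).
DEFAULT_K_LUNG = 0.05751953125
DEFAULT_K_MED = 0.05751953125


@dataclass(frozen=True)
class CompressionConfig:
    """Half-sinusoid chest-compression waveform and its pressure coupling."""

    amplitude: float = 400.0        # N
    frequency: float = 100.0        # compressions per minute
    duty_cycle: float = 0.5         # fraction of cycle with force > 0
    k_lung: float = DEFAULT_K_LUNG  # mmHg per N, intrathoracic
    k_med: float = DEFAULT_K_MED    # mmHg per N, mediastinal
    force_gate_threshold: float = 1e-9  # N; coronary flow blocked above

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 < self.duty_cycle < 1.0:
            raise ValueError("duty_cycle must lie in (0, 1)")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.k_lung < 0 or self.k_med < 0:
            raise ValueError("pressure couplings must be >= 0")

    @property
    def period(self) -> float:
        """Compression period in seconds (0.6 s at 100/min)."""
        return 60.0 / self.frequency


@dataclass(frozen=True)
class PlrConfig:
    """Passive leg raising: elevation angle and onset."""

    angle_deg: float = 90.0
    start_time: float = 20.0   # s
    leg_length: float = 0.79   # m
    ramp: float = 0.0          # s; 0 = instantaneous step

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg <= 90.0:
            raise ValueError("angle_deg must lie in [0, 90]")
        if self.start_time < 0:
            raise ValueError("start_time must be >= 0")
        if self.ramp < 0:
            raise ValueError("ramp must be >= 0")


@dataclass(frozen=True)
class ForcingProtocol:
    """Complete forcing of one simulation run."""

    compression: CompressionConfig = field(default_factory=CompressionConfig)
    plr: PlrConfig | None = None
    duration: float = 40.0  # s

    def with_plr(self, angle_deg: float, start_time: float = 20.0) -> "ForcingProtocol":
        plr = (self.plr or PlrConfig()).__class__(
            angle_deg=angle_deg, start_time=start_time,
            leg_length=self.plr.leg_length if self.plr else 0.79,
            ramp=self.plr.ramp if self.plr else 0.0,
        )
        return replace(self, plr=plr)


def compression_force(t: float, cfg: CompressionConfig) -> float:
    """Sternal force (N) at time ``t``; exactly periodic in the period."""
    if cfg.amplitude == 0.0:
        return 0.0
    period = cfg.period
    tau = t % period
    t_comp = cfg.duty_cycle * period
    if tau < t_comp:
        return cfg.amplitude * math.sin(math.pi * tau / t_comp)
    return 0.0


def force_to_pressures(force: float, cfg: CompressionConfig) -> tuple[float, float]:
    """Map sternal force (N) to (P_lung, P_M) in mmHg."""
    return cfg.k_lung * force, cfg.k_med * force


def plr_pressure(
    t: float, cfg: PlrConfig | None, rho: float = 1060.0, g: float = 9.8
) -> float:
    """Gravitational pressure (mmHg) added to both femoral compartments.

    The leg blood is modelled as a uniform column of length ``leg_length``
    whose centre of gravity sits at mid-column, so the added pressure is
    ρ·g·(l/2)·sin α (converted Pa → mmHg); zero before the onset time.
    """
    if cfg is None or t < cfg.start_time:
        return 0.0
    full = (
        rho * g * 0.5 * cfg.leg_length
        * math.sin(math.radians(cfg.angle_deg)) * MMHG_PER_PA
    )
    if cfg.ramp > 0.0 and t < cfg.start_time + cfg.ramp:
        return full * (t - cfg.start_time) / cfg.ramp
    return full


def calibrate_force_coupling(
    params: ModelParameters,
    protocol: ForcingProtocol | None = None,
    target_co: float = 1.30,
    ratio: float = 1.0,
    rel_tol: float = 1e-3,
    window: tuple[float, float] = (10.0, 20.0),
) -> tuple[float, float]:
    """Find (k_lung, k_med) that reproduce a target steady-state CO.

    A one-dimensional bisection over the common scale ``k`` (with
    ``k_med = ratio * k_lung``) of the linear force→pressure map, driven
    by the monotonicity of cardiac output in the coupling strength.
    Returns the pair once the simulated CO is within ``rel_tol`` of
    ``target_co``; raises ``RuntimeError`` reporting the achievable range
    when the target cannot be bracketed.
    """
    from .metrics import summarize
    from .model import integrate

    if target_co <= 0:
        raise ValueError("target_co must be > 0")
    if protocol is None:
        protocol = ForcingProtocol(plr=None, duration=window[1])

    def co_at(k: float) -> float:
        comp = replace(protocol.compression, k_lung=k, k_med=ratio * k)
        proto = replace(protocol, compression=comp, duration=window[1])
        trace = integrate(params, proto, dt=1e-3, duration=window[1])
        return summarize(trace, window).co

    # bracket: CO is 0 at k = 0 and increases with k
    k_lo, k_hi = 0.0, 0.05
    co_hi = co_at(k_hi)
    n_expand = 0
    while co_hi < target_co:
        k_lo, k_hi = k_hi, 2.0 * k_hi
        co_hi = co_at(k_hi)
        n_expand += 1
        if n_expand > 12:
            raise RuntimeError(
                f"cannot bracket target CO {target_co} L/min: reached only "
                f"{co_hi:.3f} L/min at coupling {k_hi:.3g} mmHg/N"
            )
    # bisection on k (co_at is monotone but not smooth: diode network)
    for _ in range(60):
        k_mid = 0.5 * (k_lo + k_hi)
        co_mid = co_at(k_mid)
        if abs(co_mid - target_co) <= rel_tol * target_co:
            return k_mid, ratio * k_mid
        if co_mid < target_co:
            k_lo = k_mid
        else:
            k_hi = k_mid
    raise RuntimeError("calibration bisection did not converge")
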