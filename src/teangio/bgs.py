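"""Background-suppression (BGS) inversion timing and null-time optimization.

Two adiabatic inversion pulses, interleaved with the PCASL labeling after a
presaturation at labeling onset, are timed so that tissue of a chosen T1
crosses zero ``t_null`` before the first readout excitation.  The classic
two-pulse solution for inversion times measured from the start of labeling
is

    t_BGS1 = TI + 2*T1_opt*ln(1/4 + 3/4 * exp(-TI/(2*T1_opt)))
    t_BGS2 = TI + 2*T1_opt*ln(3/4 + 1/4 * exp(-TI/(2*T1_opt)))

with ``TI = LD_total + PLD - t_null``.  Nulling 100 ms before the readout
(the conventional choice) leaves tissue magnetization recovering during a
long Look-Locker readout; a better target for complex subtraction is found
by a grid search over ``t_null`` that minimizes the worst acquired tissue
signal ``max_n |Mz(n) * sin(theta(n))|`` using a simple saturation-recovery
readout model (instantaneous pulses, perfect spoiling):

    Mz(1) = 1 - exp(-t_null/T1t)
    Mz(n) = 1 - (1 - Mz(n-1)*cos(theta(n-1))) * exp(-TR/T1t).

The searched variable is named ``t_null_norf`` because it ignores the
readout pulses; negative values null after the first excitation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .flip_angles import FlipAngleSchedule
from .protocol import ProtocolTimings

__all__ = [
    "BgsConfig",
    "TissueState",
    "BgsOptimum",
    "bgs_inversion_times",
    "tissue_mz_readout",
    "default_null_times",
    "optimize_null_time",
]

T1_TISSUE_DEFAULT = 1.118  # mean of white (0.791 s) and gray (1.445 s) matter


@dataclasses.dataclass(frozen=True)
class BgsConfig:
    """BGS pulse configuration (times in seconds)."""

    t1_opt: float = 0.700
    null_targets: tuple[float, float] = (0.700, 1.400)
    t_null: float = 0.100
    pld: float = 0.002
    pulse_duration: float = 0.01024

    def __post_init__(self) -> None:
        if self.t1_opt <= 0 or self.pulse_duration <= 0:
            raise ValueError("t1_opt and pulse_duration must be positive")


@dataclasses.dataclass(frozen=True)
class TissueState:
    """Longitudinal tissue magnetization history during one readout."""

    t1_tissue: float
    t_null_norf: float
    mz: np.ndarray
    signal: np.ndarray  # Mz(n) * sin(theta(n)), just after each excitation


@dataclasses.dataclass(frozen=True)
class BgsOptimum:
    """Result of the null-time grid search."""

    t_null_norf: float
    objective: float
    t_bgs1: float
    t_bgs2: float
    ti: float


def bgs_inversion_times(ti: float, t1_opt: float) -> tuple[float, float]:
    """Two-pulse inversion times from the start of labeling, for a nulling
    delay ``ti`` (see module docstring).  Raises if the timing is infeasible
    (logarithm argument non-positive, which cannot occur for ti > 0, or a
    non-ordered result)."""
    if ti <= 0:
        raise ValueError("ti must be positive")
    if t1_opt <= 0:
        raise ValueError("t1_opt must be positive")
    e = math.exp(-ti / (2.0 * t1_opt))
    a1 = 0.25 + 0.75 * e
    a2 = 0.75 + 0.25 * e
    if a1 <= 0 or a2 <= 0:
        raise ValueError("infeasible TI: logarithm argument is non-positive")
    t1 = ti + 2.0 * t1_opt * math.log(a1)
    t2 = ti + 2.0 * t1_opt * math.log(a2)
    return t1, t2


def tissue_mz_readout(
    t_null_norf: float,
    schedule: FlipAngleSchedule,
    t1_tissue: float = T1_TISSUE_DEFAULT,
    tr: float = 0.010,
) -> TissueState:
    """Tissue Mz just before each excitation and the acquired transverse
    signal, for a readout starting ``t_null_norf`` after the no-RF null."""
    if t_null_norf <= -t1_tissue * math.log(2.0):
        raise ValueError("t_null_norf must exceed -T1t*ln(2)")
    theta = schedule.angles
    n = theta.size
    decay = math.exp(-tr / t1_tissue)
    mz = np.empty(n)
    mz[0] = 1.0 - math.exp(-t_null_norf / t1_tissue)
    for i in range(1, n):
        mz[i] = 1.0 - (1.0 - mz[i - 1] * math.cos(theta[i - 1])) * decay
    return TissueState(
        t1_tissue=t1_tissue,
        t_null_norf=t_null_norf,
        mz=mz,
        signal=mz * np.sin(theta),
    )


def default_null_times(
    protocol: ProtocolTimings, cfg: BgsConfig | None = None
) -> tuple[float, float]:
    """Inversion times for the conventional setting: null ``cfg.t_null``
    (100 ms) before the first excitation."""
    cfg = cfg or BgsConfig()
    ti = protocol.ld_total + cfg.pld - cfg.t_null
    return bgs_inversion_times(ti, cfg.t1_opt)


def _feasible(ti: float, cfg: BgsConfig, ld_total: float) -> tuple[float, float] | None:
    """Inversion-onset feasibility: both pulses (duration included) must fit
    inside the labeling period without overlapping."""
    try:
        t1, t2 = bgs_inversion_times(ti, cfg.t1_opt)
    except ValueError:
        return None
    if t1 < 0:
        return None
    if t2 - t1 < cfg.pulse_duration:
        return None
    if t2 + cfg.pulse_duration > ld_total:
        return None
    return t1, t2


def optimize_null_time(
    protocol: ProtocolTimings,
    schedule: FlipAngleSchedule,
    cfg: BgsConfig | None = None,
    t1_tissue: float = T1_TISSUE_DEFAULT,
    grid_step: float = 0.001,
) -> BgsOptimum:
    """Grid search for the null time minimizing the worst acquired tissue
    signal across the readout.

    The grid spans ``(-T1t*ln 2, 1 s]`` at ``grid_step`` resolution; null
    times whose inversion pulses cannot be placed inside the labeling period
    are excluded.  Ties break toward the smallest grid value.
    """
    cfg = cfg or BgsConfig()
    if schedule.n_excitations != protocol.n_excitations:
        raise ValueError("schedule length must match the protocol")
    lo = -t1_tissue * math.log(2.0)
    start = int(math.floor(lo / grid_step)) + 1
    stop = int(round(1.0 / grid_step))
    best: BgsOptimum | None = None
    for step in range(start, stop + 1):
        t_null = step * grid_step
        ti = protocol.ld_total + cfg.pld - t_null
        if ti <= 0:
            continue
        times = _feasible(ti, cfg, protocol.ld_total)
        if times is None:
            continue
        state = tissue_mz_readout(t_null, schedule, t1_tissue, protocol.readout_tr)
        obj = float(np.max(np.abs(state.signal)))
        if best is None or obj < best.objective - 1e-15:
            best = BgsOptimum(
                t_null_norf=t_null, objective=obj, t_bgs1=times[0], t_bgs2=times[1], ti=ti
            )
    if best is None:
        raise ValueError("no feasible null time on the search grid")
    return best
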