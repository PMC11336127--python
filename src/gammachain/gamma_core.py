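"""Single-stage gamma-cycle machinery.

A cortical stage is a set of areas whose columns fire in phase within
one gamma cycle.  The reticular thalamic nucleus (RTN) acts as a
pacemaker: after each volley, RTN inhibition spaces out activity so
that the next volley can start only at the next *gate release*,
producing a strict lattice of firing opportunities with period
theta = 1000 / F (typically 25 ms at the 40 Hz human gamma rhythm).

Within a cycle, pyramidal cells integrate afferent spikes only inside
a brief excitation window before feedback inhibition (3-4 ms lag)
closes it; later spikes are discarded.  Laggard columns are first
suppressed by the fast lateral inhibitory projections of the leaders
and then facilitated, so they re-fire at the next gate release in
phase with the leaders (lateral convergence).  This suppress-then-
facilitate rule is what quantizes variable per-cell latencies onto the
gate lattice and keeps them from accumulating across stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StageConfig",
    "GateTrace",
    "PhaseEnsemble",
    "ConvergenceError",
    "gate_release_times",
    "gate_spikes",
    "column_sequence",
    "lateral_converge",
]


class ConvergenceError(RuntimeError):
    """Lateral convergence failed within the allowed number of cycles."""


@dataclass(frozen=True)
class StageConfig:
    """One pacemaker-gated cortical stage.

    Parameters
    ----------
    name
        Stage label, e.g. ``LGN_V1``, ``HO_2`` (higher-order sensory),
        ``PFC`` or ``MOTOR``.
    freq_hz
        Synchronization (gamma) frequency F of the stage.
    cycles
        Number of gamma cycles the stage consumes before handing the
        volley to the next stage.
    inhib_lag_ms
        Delay from pyramidal activation to the feedback interneuron
        volley that closes the excitation window (3-4 ms).
    window_ms_l4
        Integration window at layer 4, the narrowest (inhibition starts
        within ~3 ms there).
    window_ms_other
        Wider window of the supra/infragranular layers.
    """

    name: str
    freq_hz: float = 40.0
    cycles: int = 1
    inhib_lag_ms: float = 3.5
    window_ms_l4: float = 3.0
    window_ms_other: float = 8.0

    def __post_init__(self) -> None:
        if self.freq_hz <= 0:
            raise ValueError("freq_hz must be positive")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not (0.0 < self.window_ms_l4 <= self.window_ms_other
                < self.period_ms):
            raise ValueError(
                "windows must satisfy 0 < window_ms_l4 <= window_ms_other "
                "< period_ms")

    @property
    def period_ms(self) -> float:
        """Gamma period theta = 1000 / F in ms."""
        return 1000.0 / self.freq_hz


@dataclass(frozen=True)
class GateTrace:
    """Times at which RTN inhibition releases and columns may fire."""

    release_times_ms: np.ndarray
    period_ms: float


@dataclass
class PhaseEnsemble:
    """Per-column activation offsets within one gamma cycle."""

    phases_ms: np.ndarray
    period_ms: float

    def __post_init__(self) -> None:
        p = np.asarray(self.phases_ms, dtype=float)
        if p.size == 0:
            raise ValueError("ensemble must hold at least one column")
        if np.any(p < 0) or np.any(p >= self.period_ms):
            raise ValueError("phases must lie in [0, period_ms)")
        self.phases_ms = p

    @property
    def spread_ms(self) -> float:
        return float(self.phases_ms.max() - self.phases_ms.min())


def gate_release_times(period_ms: float, t0: float,
                       horizon_ms: float) -> GateTrace:
    """Gate lattice {t0, t0 + theta, ...} up to ``t0 + horizon_ms``.

    Returns ``floor(horizon / theta) + 1`` releases (noiseless pacing:
    consecutive differences are exactly theta).
    """
    if period_ms <= 0:
        raise ValueError("period_ms must be positive")
    if horizon_ms < 0:
        raise ValueError("horizon_ms must be non-negative")
    k = math.floor(horizon_ms / period_ms + 1e-12)
    times = t0 + period_ms * np.arange(k + 1, dtype=float)
    return GateTrace(release_times_ms=times, period_ms=period_ms)


def gate_spikes(spike_times_ms, window_start_ms: float,
                window_len_ms: float) -> np.ndarray:
    """Keep the spikes inside the excitation window.

    Returns exactly the spikes with
    ``window_start <= t < window_start + window_len``; later spikes are
    discarded, modelling the feedback inhibition that overrides late,
    weak afferents.
    """
    if window_len_ms <= 0:
        raise ValueError("window_len_ms must be positive")
    spikes = np.asarray(spike_times_ms, dtype=float)
    if spikes.size == 0:
        return spikes
    mask = (spikes >= window_start_ms) & (spikes
                                          < window_start_ms + window_len_ms)
    return spikes[mask]


def column_sequence(t_gate: float, stage: StageConfig, *,
                    relay_hop_ms: float = 2.0,
                    step_lag_ms: float = 1.0,
                    thalamic_hop_ms: float = 2.0) -> dict[str, float]:
    """Intra-column activation times for one gamma cycle.

    The feedforward volley released at ``t_gate`` traverses the column
    as: thalamic relay -> layer 4 (stellate clusters) -> layer 3 ->
    layer 5 -> layer 6 -> pulvinar (layer-5 collaterals) and RTN
    (layer-6 collaterals, whose slightly delayed inhibition is the
    spacer of the next cycle).  Thalamocortical hops are
    length-compensated by myelination and near-constant (~2 ms).

    Per-step intracortical lags are configurable; the paper-level
    constraint is only the ordering L4 < L3 < L5 < L6 (strict whenever
    ``step_lag_ms > 0``).
    """
    if t_gate < 0:
        raise ValueError("t_gate must be non-negative")
    for v in (relay_hop_ms, step_lag_ms, thalamic_hop_ms):
        if v < 0:
            raise ValueError("lags must be non-negative")
    relay = t_gate
    l4 = relay + relay_hop_ms
    l3 = l4 + step_lag_ms
    l5 = l3 + step_lag_ms
    l6 = l5 + step_lag_ms
    return {
        "relay": relay,
        "l4": l4,
        "l3": l3,
        "l5": l5,
        "l6": l6,
        "pulvinar": l5 + thalamic_hop_ms,
        "rtn_inhibition": l6 + thalamic_hop_ms,
    }


def lateral_converge(ensemble: PhaseEnsemble, tol_ms: float = 1.0,
                     max_cycles: int = 8, *,
                     rephase_jitter_sd_ms: float = 0.0,
                     rng: np.random.Generator | None = None
                     ) -> tuple[PhaseEnsemble, int]:
    """Suppress-then-facilitate convergence of column phases.

    Each cycle, columns lagging the leader (minimum phase) by more than
    ``tol_ms`` are inhibited by the fast lateral projections and, being
    facilitated, re-fire at the next gate release at the leader's phase
    (plus optional residual jitter, default 0 as re-phasing is precise).
    Returns the converged ensemble and the number of cycles used; raises
    :class:`ConvergenceError` if the spread still exceeds ``tol_ms``
    after ``max_cycles`` cycles.
    """
    if max_cycles < 1:
        raise ValueError("max_cycles must be >= 1")
    if tol_ms < 0:
        raise ValueError("tol_ms must be non-negative")
    if rephase_jitter_sd_ms > 0 and rng is None:
        rng = np.random.default_rng()

    phases = np.array(ensemble.phases_ms, dtype=float)
    cycles = 0
    while phases.max() - phases.min() > tol_ms:
        if cycles >= max_cycles:
            raise ConvergenceError(
                f"phase spread {phases.max() - phases.min():.3f} ms still "
                f"exceeds tol {tol_ms} ms after {max_cycles} cycles")
        leader = phases.min()
        laggards = phases > leader + tol_ms
        new = np.full(int(laggards.sum()), leader)
        if rephase_jitter_sd_ms > 0:
            new = new + rng.normal(0.0, rephase_jitter_sd_ms, size=new.size)
            new = np.clip(new, 0.0, np.nextafter(ensemble.period_ms, 0.0))
        phases[laggards] = new
        cycles += 1
    return PhaseEnsemble(phases_ms=phases,
                         period_ms=ensemble.period_ms), cycles
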