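"""Pipeline model of the stimulus-to-response delay.

The sensory chain is modelled as a synchronous pipeline: a succession
of pacemaker-gated cortical stages, each consuming an integer number of
gamma cycles, so the noiseless travel time is

    RT0 = afferent_delay + sum_i cycles_i * theta_i
          + entrainment_delay + motor_offset

with theta_i = 1000 / F_i.  The first stage (LGN + V1) runs at f1 and
carries the inducer-entrainment delay; higher-order sensory stages
share a common frequency f2 (T2 = 1/f2); PFC (f3) and the motor output
(f4) close the chain.  Because every stage re-quantizes its volley onto
its gate lattice, per-cell latency jitter smaller than half a period
does not propagate: the overall delay is near-deterministic despite
highly variable unit latencies.

A periodic *inducer* (the cyclic target, flashing at an alpha-band
rate) adds an attention-related inhibitory delay at the first stage of
about one third of its period P, within a limited lock range; beyond
that range locking degrades and the monotone progression of RT with P
breaks down.

Stochastic trials add: the one-frame uniform onset jitter of the
display, a uniform wait for the first gate release within [0, theta1),
a Gaussian motor/decision term, and an optional linear bias of RT on
the preceding gap.  :func:`calibrate` anchors the two free offsets
(motor_offset, motor_sd) so the analytic baseline mean/SD match the
measured session statistics; everything else is structural.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .gamma_core import StageConfig
from .protocol import (FrameClock, StimulusSchedule, GAP_MIN_MS, GAP_MAX_MS,
                       admissible_gaps, build_schedule)

__all__ = [
    "ChainConfig",
    "TrialRecord",
    "DegradedLockWarning",
    "default_config",
    "calibrated_default_config",
    "entrainment_delay",
    "is_locked",
    "noiseless_rt",
    "event_driven_rt",
    "simulate_trial",
    "simulate_session",
    "simulate_trials",
    "analytic_baseline_mean",
    "analytic_baseline_sd",
    "calibrate",
    "MEAN_GAP_MS",
]

#: Midpoint of the admissible gap range; identical for every step size.
MEAN_GAP_MS = 0.5 * (GAP_MIN_MS + GAP_MAX_MS)


class DegradedLockWarning(UserWarning):
    """Inducer period outside the full-entrainment lock range."""


@dataclass(frozen=True)
class ChainConfig:
    """Ordered stages plus the non-cortical offsets and noise terms.

    ``pregate_jitter_ms`` is the half-width of a uniform per-stage
    latency jitter applied upstream of each gate; as long as it stays
    below theta/2 the gating mechanism absorbs it completely.
    """

    stages: tuple[StageConfig, ...]
    afferent_delay_ms: float = 50.0
    motor_offset_ms: float = 0.0
    motor_sd_ms: float = 0.0
    lock_range_ms: tuple[float, float] = (55.0, 105.0)
    entrain_fraction: float = 1.0 / 3.0
    bias_slope: float = 0.0
    remove_phase_wait: bool = False
    pregate_jitter_ms: float = 0.0
    frame_ms: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        if not self.stages:
            raise ValueError("chain needs at least one stage")
        if not (0.0 < self.entrain_fraction < 1.0):
            raise ValueError("entrain_fraction must be in (0, 1)")
        lo, hi = self.lock_range_ms
        if not lo < hi:
            raise ValueError("lock_range_ms must be well ordered")
        if self.motor_sd_ms < 0 or self.pregate_jitter_ms < 0:
            raise ValueError("noise scales must be non-negative")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def theta1_ms(self) -> float:
        """Period of the first (LGN+V1) stage."""
        return self.stages[0].period_ms

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "freq_hz": s.freq_hz, "cycles": s.cycles,
                 "inhib_lag_ms": s.inhib_lag_ms,
                 "window_ms_l4": s.window_ms_l4,
                 "window_ms_other": s.window_ms_other}
                for s in self.stages
            ],
            "afferent_delay_ms": self.afferent_delay_ms,
            "motor_offset_ms": self.motor_offset_ms,
            "motor_sd_ms": self.motor_sd_ms,
            "lock_range_ms": list(self.lock_range_ms),
            "entrain_fraction": self.entrain_fraction,
            "bias_slope": self.bias_slope,
            "remove_phase_wait": self.remove_phase_wait,
            "pregate_jitter_ms": self.pregate_jitter_ms,
            "frame_ms": self.frame_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainConfig":
        d = dict(d)
        stages = tuple(StageConfig(**s) for s in d.pop("stages"))
        if "lock_range_ms" in d:
            d["lock_range_ms"] = tuple(d["lock_range_ms"])
        return cls(stages=stages, **d)


@dataclass(frozen=True)
class TrialRecord:
    """One simulated (or recorded) trial."""

    index: int
    scenario_id: str
    gap_ms: float
    onset_jitter_ms: float
    rt_ms: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", int(self.index))
        object.__setattr__(self, "gap_ms", float(self.gap_ms))
        object.__setattr__(self, "onset_jitter_ms",
                           float(self.onset_jitter_ms))
        object.__setattr__(self, "rt_ms", float(self.rt_ms))
        if self.rt_ms < 0:
            raise ValueError("rt_ms must be non-negative")


def default_config() -> ChainConfig:
    """Default roster: LGN+V1, five higher-order sensory stages, PFC,
    motor — all at 40 Hz, one cycle each — with a 50 ms afferent delay.

    The stage count is a free parameter of the model (the number of
    cortical stages is an open empirical question); calibration absorbs
    any residual time into ``motor_offset_ms``, so the anchored mean
    does not depend on the roster.
    """
    stages = [StageConfig("LGN_V1")]
    stages += [StageConfig(f"HO_{k}") for k in range(1, 6)]
    stages += [StageConfig("PFC"), StageConfig("MOTOR")]
    return ChainConfig(stages=tuple(stages))


def is_locked(P_ms: float | None, config: ChainConfig) -> bool:
    """True when the inducer period falls in the full-entrainment range."""
    if P_ms is None:
        return False
    lo, hi = config.lock_range_ms
    return lo <= P_ms <= hi


def entrainment_delay(P_ms: float | None, config: ChainConfig) -> float:
    """Extra first-stage delay induced by a periodic distractor.

    The alpha-band attentional inhibition locked onto the cyclic target
    delays the attended target's processing by about one third of the
    inducer period: fraction * P for P inside the lock range.  Outside
    the range locking degrades; the delay saturates at the nearest
    range edge and a :class:`DegradedLockWarning` is emitted (the
    saturation value is a placeholder, not a prediction).
    """
    if P_ms is None:
        return 0.0
    if P_ms <= 0:
        raise ValueError("inducer period must be positive")
    lo, hi = config.lock_range_ms
    if P_ms > hi:
        warnings.warn(
            f"inducer period {P_ms} ms exceeds the lock range "
            f"({lo}, {hi}) ms; entrainment saturated", DegradedLockWarning,
            stacklevel=2)
        return config.entrain_fraction * hi
    if P_ms < lo:
        warnings.warn(
            f"inducer period {P_ms} ms is below the lock range "
            f"({lo}, {hi}) ms; entrainment saturated", DegradedLockWarning,
            stacklevel=2)
        return config.entrain_fraction * lo
    return config.entrain_fraction * P_ms


def noiseless_rt(config: ChainConfig, entrain_delay_ms: float = 0.0) -> float:
    """Closed-form pipeline delay: afferent + sum(cycles * theta) +
    entrainment + motor offset.  No randomness."""
    t = config.afferent_delay_ms
    for i, stage in enumerate(config.stages):
        t = t + stage.cycles * stage.period_ms
        if i == 0:
            t = t + entrain_delay_ms
    return t + config.motor_offset_ms


def event_driven_rt(config: ChainConfig, entrain_delay_ms: float = 0.0,
                    stage_jitter_ms=None) -> float:
    """Event-driven traversal of the chain with explicit gate snapping.

    Each stage's gate lattice is phase-locked (by the pulvinar-mediated
    lateral convergence) onto the nominal arrival time of the volley.
    A jittered arrival is re-quantized to the nearest gate release, so
    any per-stage jitter smaller than theta/2 leaves the output time
    bit-for-bit unchanged; larger jitter slips by whole cycles.
    """
    if stage_jitter_ms is not None:
        stage_jitter_ms = np.asarray(stage_jitter_ms, dtype=float)
        if stage_jitter_ms.size != len(config.stages):
            raise ValueError("one jitter value per stage expected")
    t = config.afferent_delay_ms
    for i, stage in enumerate(config.stages):
        theta = stage.period_ms
        xi = 0.0 if stage_jitter_ms is None else float(stage_jitter_ms[i])
        arrival = t + xi
        gate = t + theta * round((arrival - t) / theta)
        t = gate + stage.cycles * theta
        if i == 0:
            t = t + entrain_delay_ms
    return t + config.motor_offset_ms


def simulate_trial(config: ChainConfig, gap_ms: float,
                   rng: np.random.Generator, *,
                   cyclic_period_ms: float | None = None,
                   mean_gap_ms: float = MEAN_GAP_MS,
                   jitter_rng: np.random.Generator | None = None,
                   index: int = 0,
                   scenario_id: str = "baseline") -> TrialRecord:
    """One trial: structural delay plus the stochastic terms.

    rt = RT0(entrainment) + onset jitter U[0, frame)
         + first-gate phase wait U[0, theta1)
         + N(0, motor_sd) + bias_slope * (gap - mean gap),  clipped at 0.

    When ``config.remove_phase_wait`` is set and the inducer is inside
    the lock range, the uniform phase wait is zeroed (gate phase-locked
    to the stimulus); by default the entrainment delay is purely
    additive, which reproduces the observed mean shift of exactly
    fraction * P between cyclic and baseline conditions.
    """
    delay = entrainment_delay(cyclic_period_ms, config)
    if config.pregate_jitter_ms > 0:
        jr = jitter_rng if jitter_rng is not None else rng
        xi = jr.uniform(-config.pregate_jitter_ms, config.pregate_jitter_ms,
                        size=len(config.stages))
        base = event_driven_rt(config, delay, xi)
    else:
        base = noiseless_rt(config, delay)

    jitter = float(rng.uniform(0.0, config.frame_ms))
    locked = is_locked(cyclic_period_ms, config)
    if locked and config.remove_phase_wait:
        wait = 0.0
    else:
        wait = float(rng.uniform(0.0, config.theta1_ms))
    motor = float(rng.normal(0.0, config.motor_sd_ms)) \
        if config.motor_sd_ms > 0 else 0.0
    rt = (base + jitter + wait + motor
          + config.bias_slope * (gap_ms - mean_gap_ms))
    return TrialRecord(index=index, scenario_id=scenario_id,
                       gap_ms=float(gap_ms), onset_jitter_ms=jitter,
                       rt_ms=max(rt, 0.0))


def simulate_session(config: ChainConfig, schedule: StimulusSchedule,
                     contaminate: float = 0.06,
                     seed: int | np.random.SeedSequence = 0
                     ) -> list[TrialRecord]:
    """Simulate every random target of a schedule.

    A ``contaminate`` fraction of trials is replaced by erratic strikes
    with rt uniform on [0, 200) ms, emulating the erroneous key presses
    removed later by the 200 ms screen.  Fully reproducible for a fixed
    seed (separate sub-streams for trial noise, pre-gate jitter and
    contamination, so enabling jitter does not perturb the other draws).
    """
    if not 0.0 <= contaminate <= 0.2:
        raise ValueError("contaminate must lie in [0, 0.2]")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    r_trial, r_jit, r_cont = (np.random.default_rng(s) for s in ss.spawn(3))

    with warnings.catch_warnings():
        # one warning per session is enough for an out-of-range inducer
        warnings.simplefilter("once", DegradedLockWarning)
        records = [
            simulate_trial(config, gap, r_trial,
                           cyclic_period_ms=schedule.cyclic_period_ms,
                           jitter_rng=r_jit, index=i,
                           scenario_id=schedule.scenario_id)
            for i, gap in enumerate(schedule.gaps_ms)
        ]
    if contaminate > 0:
        strike = r_cont.random(len(records)) < contaminate
        for i in np.flatnonzero(strike):
            records[i] = replace(records[i],
                                 rt_ms=float(r_cont.uniform(0.0, 200.0)))
    return records


def simulate_trials(config: ChainConfig, scenario_id: str, n_trials: int, *,
                    contaminate: float = 0.06,
                    seed: int | np.random.SeedSequence = 0,
                    clock: FrameClock = FrameClock()) -> list[TrialRecord]:
    """Convenience wrapper: build a long-enough schedule, simulate, and
    truncate to exactly ``n_trials`` records."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_sched, s_sess = ss.spawn(2)
    duration = (n_trials + 8) * GAP_MAX_MS
    sched = build_schedule(scenario_id, duration, clock, seed=s_sched)
    records = simulate_session(config, sched, contaminate, seed=s_sess)
    return records[:n_trials]


def _gap_variance(step_ms: float) -> float:
    vals = admissible_gaps(step_ms)
    return float(np.var(vals))


def analytic_baseline_mean(config: ChainConfig) -> float:
    """Expected baseline-trial RT: RT0 + frame/2 + theta1/2."""
    return (noiseless_rt(config, 0.0) + 0.5 * config.frame_ms
            + 0.5 * config.theta1_ms)


def analytic_baseline_sd(config: ChainConfig, gap_step_ms: float = 60.0
                         ) -> float:
    """Baseline RT standard deviation from the variance decomposition:
    uniform frame jitter + uniform gate-phase wait + Gaussian motor
    term (+ gap-bias term when bias_slope != 0)."""
    var = (config.frame_ms ** 2 / 12.0 + config.theta1_ms ** 2 / 12.0
           + config.motor_sd_ms ** 2
           + config.bias_slope ** 2 * _gap_variance(gap_step_ms))
    return math.sqrt(var)


def calibrate(config: ChainConfig, target_mean_ms: float = 281.0,
              target_sd_ms: float = 38.0) -> ChainConfig:
    """Anchor the free offsets to measured baseline statistics.

    Solves ``motor_offset_ms`` so the analytic baseline mean equals
    ``target_mean_ms`` and ``motor_sd_ms`` so the analytic baseline SD
    equals ``target_sd_ms``.  The structural variance floor
    (frame jitter + gate-phase wait [+ gap bias]) bounds the feasible
    SD from below; a target below it raises ``ValueError``.
    """
    base = replace(config, motor_offset_ms=0.0, motor_sd_ms=0.0)
    offset = target_mean_ms - analytic_baseline_mean(base)
    if offset < 0:
        raise ValueError(
            f"target mean {target_mean_ms} ms is below the structural "
            f"delay {analytic_baseline_mean(base):.1f} ms")
    floor_var = (config.frame_ms ** 2 / 12.0 + config.theta1_ms ** 2 / 12.0
                 + config.bias_slope ** 2 * _gap_variance(60.0))
    if target_sd_ms ** 2 <= floor_var:
        raise ValueError(
            f"target SD {target_sd_ms} ms is below the structural floor "
            f"{math.sqrt(floor_var):.2f} ms")
    sd = math.sqrt(target_sd_ms ** 2 - floor_var)
    return replace(config, motor_offset_ms=offset, motor_sd_ms=sd)


def calibrated_default_config(target_mean_ms: float = 281.0,
                              target_sd_ms: float = 38.0) -> ChainConfig:
    """Default roster calibrated to the measured baseline statistics
    (mean 281 ms, SD 38 ms over 1018 screened trials)."""
    return calibrate(default_config(), target_mean_ms, target_sd_ms)
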