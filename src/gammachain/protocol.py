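"""Frame-accurate stimulus schedules for the flashed-target protocol.

The protocol flashes a bright *random target* for a single video frame
(20 ms on a 50 Hz monitor) at a fixed central position over a dark
background.  Successive random targets are separated by a gap drawn
equiprobably from the multiples of a step inside [1.2 s, 2.4 s]; the
step is 60 ms in the baseline scenario and equals the inducer period P
in the cyclic scenarios.

In the cyclic scenarios a dimmer *cyclic target* flashes every P ms
(P in {60, 80, 100, 120}).  The random target always *replaces* a
scheduled cyclic flash, so it is strictly in phase with the inducer:
random onsets lie on the cyclic lattice and no cyclic target is drawn
at those slots.

Because the stimulus software cannot synchronize onto the video
refresh, the physical onset carries a uniform jitter of one frame
(``onset_jitter``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrameClock",
    "StimulusSchedule",
    "SCENARIO_PERIODS",
    "GAP_MIN_MS",
    "GAP_MAX_MS",
    "BASELINE_STEP_MS",
    "admissible_gaps",
    "build_schedule",
    "onset_jitter",
    "schedule_to_frame",
    "write_schedule",
]

GAP_MIN_MS = 1200.0
GAP_MAX_MS = 2400.0
BASELINE_STEP_MS = 60.0

#: Scenario label -> cyclic inducer period in ms (None = no inducer).
SCENARIO_PERIODS: dict[str, float | None] = {
    "baseline": None,
    "cyclic60": 60.0,
    "cyclic80": 80.0,
    "cyclic100": 100.0,
    "cyclic120": 120.0,
}

_TOL = 1e-9


@dataclass(frozen=True)
class FrameClock:
    """Video refresh clock.  Default: 50 Hz, i.e. one frame every 20 ms."""

    frame_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.frame_ms <= 0:
            raise ValueError(f"frame_ms must be positive, got {self.frame_ms}")

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.frame_ms


def admissible_gaps(step_ms: float) -> np.ndarray:
    """Multiples of ``step_ms`` inside [GAP_MIN_MS, GAP_MAX_MS], inclusive."""
    if step_ms <= 0:
        raise ValueError("step_ms must be positive")
    k0 = math.ceil(GAP_MIN_MS / step_ms - _TOL)
    k1 = math.floor(GAP_MAX_MS / step_ms + _TOL)
    if k1 < k0:
        raise ValueError(f"no multiple of {step_ms} ms falls in "
                         f"[{GAP_MIN_MS}, {GAP_MAX_MS}] ms")
    return step_ms * np.arange(k0, k1 + 1, dtype=float)


@dataclass
class StimulusSchedule:
    """Nominal (pre-jitter) onset times of one session's targets.

    All times are in ms from session start; the cyclic lattice is
    anchored at t = 0.
    """

    scenario_id: str
    duration_ms: float
    frame_ms: float
    cyclic_period_ms: float | None
    random_onsets_ms: np.ndarray
    cyclic_onsets_ms: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=float))
    gaps_ms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    @property
    def n_trials(self) -> int:
        return int(len(self.random_onsets_ms))

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        r = np.asarray(self.random_onsets_ms, dtype=float)
        if r.size == 0:
            raise ValueError("schedule holds no random target")
        if np.any(np.diff(r) <= 0):
            raise ValueError("random onsets must be strictly increasing")
        frac = np.abs(r / self.frame_ms - np.round(r / self.frame_ms))
        if np.any(frac > _TOL):
            raise ValueError("random onsets must align to video frames")
        step = (self.cyclic_period_ms if self.cyclic_period_ms is not None
                else BASELINE_STEP_MS)
        allowed = admissible_gaps(step)
        g = np.asarray(self.gaps_ms, dtype=float)
        if g.size != r.size:
            raise ValueError("one gap per random target expected")
        if not np.all(np.isin(np.round(g, 6), np.round(allowed, 6))):
            raise ValueError("gap outside the admissible set")
        if self.cyclic_period_ms is not None:
            P = self.cyclic_period_ms
            phase = np.abs(r / P - np.round(r / P))
            if np.any(phase > _TOL):
                raise ValueError("random onset off the cyclic lattice")
            c = np.asarray(self.cyclic_onsets_ms, dtype=float)
            if np.intersect1d(np.round(c, 6), np.round(r, 6)).size:
                raise ValueError("cyclic target drawn at a random-target slot")


def build_schedule(scenario_id: str,
                   duration_ms: float = 300_000.0,
                   clock: FrameClock = FrameClock(),
                   seed: int | np.random.SeedSequence = 0) -> StimulusSchedule:
    """Draw one session's stimulus schedule.

    Gaps between random targets are i.i.d. equiprobable over the
    admissible multiples; the first target is placed one gap after
    session start.  For cyclic scenarios the full inducer lattice
    {0, P, 2P, ...} is emitted minus the slots taken over by random
    targets (replacement rule).  Deterministic for a fixed ``seed``.
    """
    if scenario_id not in SCENARIO_PERIODS:
        raise ValueError(f"unknown scenario {scenario_id!r}; expected one of "
                         f"{sorted(SCENARIO_PERIODS)}")
    if duration_ms < 3000:
        raise ValueError("duration_ms must be at least 3000 ms to place "
                         "one random target")
    period = SCENARIO_PERIODS[scenario_id]
    if period is not None and abs(period % clock.frame_ms) > _TOL:
        raise ValueError(f"cyclic period {period} ms is not a multiple of "
                         f"the {clock.frame_ms} ms video frame")
    step = period if period is not None else BASELINE_STEP_MS
    pool = admissible_gaps(step)

    rng = np.random.default_rng(seed)
    onsets: list[float] = []
    gaps: list[float] = []
    t = 0.0
    while True:
        g = float(pool[rng.integers(0, len(pool))])
        if t + g > duration_ms:
            break
        t += g
        onsets.append(t)
        gaps.append(g)
    random_onsets = np.asarray(onsets, dtype=float)

    if period is not None:
        lattice = period * np.arange(0, math.floor(duration_ms / period) + 1,
                                     dtype=float)
        cyclic_onsets = np.setdiff1d(np.round(lattice, 6),
                                     np.round(random_onsets, 6))
    else:
        cyclic_onsets = np.empty(0, dtype=float)

    sched = StimulusSchedule(
        scenario_id=scenario_id,
        duration_ms=float(duration_ms),
        frame_ms=clock.frame_ms,
        cyclic_period_ms=period,
        random_onsets_ms=random_onsets,
        cyclic_onsets_ms=cyclic_onsets,
        gaps_ms=np.asarray(gaps, dtype=float),
    )
    sched.validate()
    return sched


def onset_jitter(onset_ms: float,
                 clock: FrameClock = FrameClock(),
                 rng: np.random.Generator | None = None) -> float:
    """Physical onset = nominal onset + uniform [0, frame) ms.

    Models the lack of stimulus/refresh synchronization: the target is
    painted at the next frame boundary, uniformly late by up to one
    frame.  Expectation of the added term is frame/2.
    """
    if onset_ms < 0:
        raise ValueError("onset_ms must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    return float(onset_ms + rng.uniform(0.0, clock.frame_ms))


def schedule_to_frame(schedule: StimulusSchedule) -> pd.DataFrame:
    """Long-form table of all events: (event_type, onset_ms, frame_index)."""
    rows = []
    for t in schedule.random_onsets_ms:
        rows.append(("random", float(t), int(round(t / schedule.frame_ms))))
    for t in schedule.cyclic_onsets_ms:
        rows.append(("cyclic", float(t), int(round(t / schedule.frame_ms))))
    df = pd.DataFrame(rows, columns=["event_type", "onset_ms", "frame_index"])
    return df.sort_values("onset_ms", kind="stable").reset_index(drop=True)


def write_schedule(schedule: StimulusSchedule, path) -> None:
    """Serialize a schedule to CSV (byte-stable for a fixed seed)."""
    schedule_to_frame(schedule).to_csv(path, index=False, float_format="%.3f")
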