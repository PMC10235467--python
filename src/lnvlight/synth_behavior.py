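"""Synthetic TriKinetics-style activity data with controlled sleep and arousal.

Each fly is an alternating renewal process: wake bouts (1 + Poisson(mean - 1) beam
crossings per minute, so an awake minute always registers at least one crossing)
alternate with sleep bouts (zero counts).  Sleep bouts are 5 min plus an exponential
tail so every generated bout satisfies the standard >= 5-min fly-sleep criterion and
zero-count minutes coincide exactly with sleep minutes, making the analysis-side
classifier and the generator agree on ground truth.  Bout-length means
differ between day (ZT0-12) and night (ZT12-24) so files show realistic diurnal
structure; day-phase activity is irrelevant to arousal scoring but exercises the
dead-fly filter.

Light-pulse arousal is a per-pulse Bernoulli applied to flies asleep going into the
onset minute: an aroused fly wakes at the onset minute and stays active for a
geometric number of minutes (mean 10); a fly that sleeps through has its bout
extended past the pulse window, implementing "else its bout continues" — without the
extension, natural bout terminations at or inside the 5-min window would inflate the
recovered arousal probability by several percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .io_formats import DAM_N_CHANNELS, DamRecord
from .synth_ephys import stable_seed

MINUTES_PER_DAY = 1440


@dataclass
class PulseSchedule:
    """Nighttime light-pulse protocol: 5-min pulses at ZT18/19/20 for three nights."""

    pulse_zt_hours: tuple[int, ...] = (18, 19, 20)
    pulse_minutes: int = 5
    nights: int = 3
    wavelength: int = 365
    intensity: float = 10.0  # uW/cm2, low (10) or high (400)

    def __post_init__(self) -> None:
        if any(not (12 <= h < 24) for h in self.pulse_zt_hours):
            raise ValueError("pulses must fall within subjective night (ZT12-24)")
        onsets = sorted(h * 60 for h in self.pulse_zt_hours)
        if any(b - a < self.pulse_minutes for a, b in zip(onsets, onsets[1:])):
            raise ValueError("pulses overlap")


@dataclass
class BehaviorGenotypeParams:
    """Generative behavior parameters for one genotype.

    ``arousal_prob`` maps (wavelength nm, intensity uW/cm2) to the per-pulse
    probability that a sleeping fly awakens.  Bout-length means are in minutes;
    ``activity_mean`` (>= 1) is the mean beam crossings per awake minute, drawn as
    1 + Poisson(activity_mean - 1) so awake minutes are never silent.
    """

    arousal_prob: dict[tuple[int, float], float] = field(default_factory=dict)
    sleep_bout_mean_night: float = 45.0
    wake_bout_mean_night: float = 10.0
    sleep_bout_mean_day: float = 20.0
    wake_bout_mean_day: float = 60.0
    activity_mean: float = 2.0
    arousal_activity_mean_minutes: float = 10.0

    def __post_init__(self) -> None:
        for key, p in self.arousal_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"arousal probability {p} for {key} outside [0, 1]")
        if min(self.sleep_bout_mean_night, self.sleep_bout_mean_day) < 5:
            raise ValueError("mean sleep-bout length must be >= 5 min")
        if self.activity_mean < 1:
            raise ValueError("activity_mean must be >= 1 crossing per awake minute")

    def p_for(self, schedule: PulseSchedule) -> float:
        return self.arousal_prob[(schedule.wavelength, schedule.intensity)]


def pulse_onset_indices(
    n_minutes: int, offset_zt_min: int, schedule: PulseSchedule
) -> list[int]:
    """Minute indices of pulse onsets for the first ``schedule.nights`` nights.

    ``offset_zt_min`` is the ZT minute-of-cycle of row 0 (0 when the recording starts
    at ZT0).  Raises if fewer than ``nights`` nights with complete pulse windows fit.
    """
    onsets: list[int] = []
    nights_found = 0
    day = offset_zt_min // MINUTES_PER_DAY
    while nights_found < schedule.nights:
        night_onsets = []
        complete = True
        for h in sorted(schedule.pulse_zt_hours):
            idx = day * MINUTES_PER_DAY + h * 60 - offset_zt_min
            if idx < 0 or idx + schedule.pulse_minutes > n_minutes:
                complete = False
                break
            night_onsets.append(idx)
        if complete:
            onsets.extend(night_onsets)
            nights_found += 1
        elif night_onsets or day * MINUTES_PER_DAY - offset_zt_min >= n_minutes:
            raise ValueError(
                f"recording too short: only {nights_found} of {schedule.nights} "
                "pulse nights fit"
            )
        day += 1
    return onsets


def simulate_fly_activity(
    params: BehaviorGenotypeParams,
    schedule: PulseSchedule,
    days: int,
    seed: int,
    offset_zt_min: int = 0,
) -> np.ndarray:
    """One fly channel's 1-min beam-crossing counts over ``days`` days.

    The fly alternates wake and sleep bouts; at each pulse onset a fly that was
    asleep through the preceding minute awakens with probability
    ``params.p_for(schedule)``, emitting counts within the pulse window, otherwise
    its sleep bout continues through the window (a bout whose sampled end coincides
    with the onset is likewise governed by the Bernoulli, so pulse-window activity
    from a sleeping fly occurs exactly when the arousal coin says so).
    Deterministic under ``seed``.
    """
    if days < schedule.nights:
        raise ValueError("days must cover the scheduled pulse nights")
    p_arousal = params.p_for(schedule)
    rng = np.random.default_rng(seed)
    n = days * MINUTES_PER_DAY
    onsets = set(pulse_onset_indices(n, offset_zt_min, schedule))
    counts = np.zeros(n, dtype=int)

    def is_night(i: int) -> bool:
        return ((offset_zt_min + i) % MINUTES_PER_DAY) >= 720

    def sample_bout(state: str, i: int) -> int:
        if state == "sleep":
            mean = params.sleep_bout_mean_night if is_night(i) else params.sleep_bout_mean_day
            return 5 + int(round(rng.exponential(mean - 5)))
        mean = params.wake_bout_mean_night if is_night(i) else params.wake_bout_mean_day
        return max(1, int(round(rng.exponential(mean))))

    state = "wake" if rng.random() < 0.5 else "sleep"
    remaining = sample_bout(state, 0)
    prev_sleep = False
    for i in range(n):
        if i in onsets and prev_sleep:
            if rng.random() < p_arousal:
                state = "wake"
                remaining = 1 + rng.geometric(1.0 / params.arousal_activity_mean_minutes)
            else:
                # bout continues through the whole pulse window (re-entering sleep
                # if the sampled bout end coincided with the onset)
                still_asleep = state == "sleep"
                state = "sleep"
                remaining = max(remaining if still_asleep else 0,
                                schedule.pulse_minutes + 1)
        if state == "wake":
            counts[i] = 1 + int(rng.poisson(params.activity_mean - 1))
        prev_sleep = state == "sleep"
        remaining -= 1
        if remaining <= 0:
            state = "sleep" if state == "wake" else "wake"
            remaining = sample_bout(state, i + 1)
    return counts


def simulate_dam_cohort(
    params: BehaviorGenotypeParams,
    genotype: str,
    n_flies: int,
    schedule: PulseSchedule,
    master_seed: int,
    days: int = 4,
    start: datetime | None = None,
    zt0_hour: float = 8.0,
) -> list[DamRecord]:
    """Simulate a cohort as one or more 32-channel monitor records.

    Cohorts larger than 32 flies are split across monitors; unused channels are
    zero-filled.  The light-status column marks pulse minutes.  Recordings start at
    ZT0 (``start`` defaults to lights-on on 2024-01-01 at ``zt0_hour`` local).
    Byte-identical across reruns for a fixed ``master_seed``.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    if start is None:
        start = datetime(2024, 1, 1, int(zt0_hour), int(round((zt0_hour % 1) * 60)))
    n = days * MINUTES_PER_DAY
    times = np.datetime64(start, "m") + np.arange(n).astype("timedelta64[m]")
    light = np.zeros(n, dtype=int)
    # entraining 12:12 LD lights plus the pulse minutes
    zt_min = np.arange(n) % MINUTES_PER_DAY
    light[zt_min < 720] = 1
    for onset in pulse_onset_indices(n, 0, schedule):
        light[onset : onset + schedule.pulse_minutes] = 1
    records = []
    for monitor_idx in range(0, n_flies, DAM_N_CHANNELS):
        n_here = min(DAM_N_CHANNELS, n_flies - monitor_idx)
        counts = np.zeros((n, DAM_N_CHANNELS), dtype=int)
        for ch in range(n_here):
            fly = monitor_idx + ch + 1
            counts[:, ch] = simulate_fly_activity(
                params,
                schedule,
                days,
                stable_seed(master_seed, genotype, "fly", fly),
            )
        records.append(
            DamRecord(
                monitor_id=monitor_idx // DAM_N_CHANNELS + 1,
                times=times,
                counts=counts,
                light=light,
                zt0_hour=zt0_hour,
            )
        )
    return records


__all__ = [
    "BehaviorGenotypeParams",
    "MINUTES_PER_DAY",
    "PulseSchedule",
    "pulse_onset_indices",
    "simulate_dam_cohort",
    "simulate_fly_activity",
]
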