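"""Sleep classification and light-pulse arousal scoring from monitor data.

Sleep follows the standard Drosophila criterion: a minute is asleep iff it lies inside
a maximal run of >= 5 consecutive zero-count minutes.  For each scheduled 5-min light
pulse, a fly enters the denominator iff it was asleep at pulse onset (the 5 minutes
immediately before the onset all zero) and counts as aroused iff it registers >= 1
beam crossing within the pulse window.  Flies with zero counts over the final 24 h of
the recording are excluded as dead.

Summaries report the nine per-pulse percentages (3 nights x 3 pulses), per-night
means (for the night-consistency check), and a total average that is
denominator-weighted by default (an unweighted mean of the nine values is available,
since the source aggregation convention is not pinned down).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import DamRecord
from .synth_behavior import MINUTES_PER_DAY, PulseSchedule, pulse_onset_indices

logger = logging.getLogger(__name__)

SLEEP_MIN_BOUT = 5


@dataclass
class SleepSeries:
    """Per-minute sleep states for one fly plus the bout list."""

    asleep: np.ndarray  # bool per minute
    bouts: list[tuple[int, int]]  # (start minute index, duration in minutes)


def classify_sleep(counts: np.ndarray, min_bout: int = SLEEP_MIN_BOUT) -> SleepSeries:
    """Classify each minute as sleep/wake by the >= ``min_bout``-min inactivity rule."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    zero = counts == 0
    asleep = np.zeros(counts.size, dtype=bool)
    bouts: list[tuple[int, int]] = []
    run_starts = np.flatnonzero(np.diff(np.concatenate(([0], zero.view(np.int8)))) == 1)
    run_stops = np.flatnonzero(np.diff(np.concatenate((zero.view(np.int8), [0]))) == -1) + 1
    for s, e in zip(run_starts, run_stops):
        if e - s >= min_bout:
            asleep[s:e] = True
            bouts.append((int(s), int(e - s)))
    return SleepSeries(asleep=asleep, bouts=bouts)


def score_pulse_arousal(
    record: DamRecord,
    schedule: PulseSchedule,
    channels: list[int] | None = None,
    grace_minutes: int = 0,
    denominator: str = "sleeping",
) -> pd.DataFrame:
    """Score every scheduled pulse for every live fly in ``record``.

    Returns a DataFrame with one row per (night, pulse, fly) and columns
    ``night`` (1-based), ``pulse_zt``, ``channel`` (1-based), ``asleep_at_onset`` and
    ``aroused``.  Dead flies (zero counts over the final 24 h) are excluded entirely
    and logged.  Raises if a scheduled pulse falls outside the recording or the rows
    are not contiguous minutes.

    ``grace_minutes`` extends the arousal window past the pulse (default: the 5-min
    pulse only).  ``denominator="all"`` marks every live fly as eligible instead of
    only those asleep at onset, for sensitivity analyses.
    """
    if denominator not in ("sleeping", "all"):
        raise ValueError("denominator must be 'sleeping' or 'all'")
    n = record.n_minutes
    if n > 1:
        diffs = np.diff(record.times) / np.timedelta64(1, "m")
        if np.any(diffs != 1):
            raise ValueError("record has timestamp gaps; arousal scoring needs contiguous minutes")
    offset = int(record.zt_minutes()[0])
    onsets = pulse_onset_indices(n, offset, schedule)  # raises if pulses don't fit
    pulse_hours = sorted(schedule.pulse_zt_hours)
    if channels is None:
        channels = list(range(1, record.counts.shape[1] + 1))
    final_day = record.counts[max(0, n - MINUTES_PER_DAY):, :]
    dead = [ch for ch in channels if final_day[:, ch - 1].sum() == 0]
    if dead:
        logger.warning("score_pulse_arousal: %d dead channel(s) excluded: %s", len(dead), dead)
    live = [ch for ch in channels if ch not in dead]
    rows = []
    for j, onset in enumerate(onsets):
        night = j // len(pulse_hours) + 1
        pulse_zt = pulse_hours[j % len(pulse_hours)]
        if onset < SLEEP_MIN_BOUT:
            raise ValueError("pulse onset too close to recording start to assess sleep")
        window_end = min(onset + schedule.pulse_minutes + grace_minutes, n)
        for ch in live:
            v = record.counts[:, ch - 1]
            asleep = bool(np.all(v[onset - SLEEP_MIN_BOUT : onset] == 0))
            eligible = asleep if denominator == "sleeping" else True
            aroused = eligible and bool(np.any(v[onset:window_end] > 0))
            rows.append(
                {
                    "night": night,
                    "pulse_zt": pulse_zt,
                    "channel": ch,
                    "asleep_at_onset": asleep,
                    "eligible": eligible,
                    "aroused": aroused,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ArousalSummary:
    """Per-condition arousal summary mirroring one cell of the behavioral table."""

    genotype: str
    wavelength: int
    intensity: float
    per_pulse_pct: pd.DataFrame  # night, pulse_zt, n_asleep, n_aroused, pct
    total_pct: float  # total average % aroused (0-100)
    per_night_pct: pd.Series  # mean % per night
    weighted: bool = True


def summarize_arousal(
    outcomes: pd.DataFrame,
    genotype: str,
    wavelength: int,
    intensity: float,
    weighted: bool = True,
) -> ArousalSummary:
    """Summarize per-pulse outcomes into the nine per-pulse percentages and the total.

    ``weighted=True`` computes the total as sum(aroused)/sum(asleep) over all pulses
    (denominator-weighted); ``weighted=False`` takes the unweighted mean of the nine
    per-pulse percentages.  Raises when no fly was asleep at any pulse onset.
    """
    if outcomes.empty:
        raise ValueError("no scored pulses")
    denom_col = "eligible" if "eligible" in outcomes.columns else "asleep_at_onset"
    grouped = (
        outcomes.groupby(["night", "pulse_zt"])
        .agg(n_asleep=(denom_col, "sum"), n_aroused=("aroused", "sum"))
        .reset_index()
    )
    if grouped["n_asleep"].sum() == 0:
        raise ValueError("no flies asleep at any pulse onset; empty summary")
    grouped["pct"] = 100.0 * grouped["n_aroused"] / grouped["n_asleep"].replace(0, np.nan)
    if weighted:
        total = 100.0 * grouped["n_aroused"].sum() / grouped["n_asleep"].sum()
    else:
        total = float(grouped["pct"].mean())
    per_night = grouped.groupby("night").apply(
        lambda g: 100.0 * g["n_aroused"].sum() / g["n_asleep"].sum(), include_groups=False
    )
    return ArousalSummary(
        genotype=genotype,
        wavelength=wavelength,
        intensity=intensity,
        per_pulse_pct=grouped,
        total_pct=float(total),
        per_night_pct=per_night,
        weighted=weighted,
    )


__all__ = [
    "ArousalSummary",
    "SLEEP_MIN_BOUT",
    "SleepSeries",
    "classify_sleep",
    "score_pulse_arousal",
    "summarize_arousal",
]
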