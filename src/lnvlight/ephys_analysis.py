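"""Firing-frequency analysis of l-LNv voltage traces.

The chain runs: spike detection on the high-pass-filtered trace (robust MAD threshold,
2-ms refractory floor) -> protocol-aligned 10-s binning -> per-sweep firing-frequency
(FF) ratio and post-stimulus profile -> per-cell sweep averaging -> per-group mean +/-
SEM.

The FF ratio is a rate ratio: (light-on spikes / 5 s) / (pre-light spikes / 50 s).
Both sides are converted to Hz before dividing so that the 5-s light window and the
10-s baseline bins are on a common scale.  The post-stimulus profile divides each of
the five 10-s post bins (as Hz) by the same baseline rate.  Bins are half-open
[start, end): a spike at exactly lights-on belongs to the light-on window.

Cells whose pre-light window contains no spikes have an undefined ratio; they are
excluded from group aggregation with the exclusion count reported, never assigned an
infinite ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_formats import TraceFile, TraceMeta
from .synth_ephys import SpikeTrain, SweepProtocol

logger = logging.getLogger(__name__)

#: robust-sigma multiplier for the detection threshold (Quiroga convention:
#: sigma_hat = MAD / 0.6745, threshold = THRESHOLD_SIGMA * sigma_hat)
THRESHOLD_SIGMA = 5.0
HIGHPASS_HZ = 50.0
REFRACTORY_FLOOR_S = 0.002
_MAD_TO_SIGMA = 0.6745


def detect_spikes(
    trace: TraceFile,
    protocol: SweepProtocol | None = None,
    threshold_sigma: float = THRESHOLD_SIGMA,
    highpass_hz: float = HIGHPASS_HZ,
    min_separation: float = REFRACTORY_FLOOR_S,
) -> SpikeTrain:
    """Detect action potentials in a voltage trace.

    The trace is zero-phase high-pass filtered (2nd-order Butterworth) to remove the
    resting potential, the light-step DC depolarization and slow drift; the threshold
    is ``threshold_sigma`` robust standard deviations of the filtered signal
    (sigma estimated as MAD/0.6745).  One event is emitted per suprathreshold
    excursion, timed at its peak sample; events closer than ``min_separation`` are
    collapsed onto the earlier peak with a logged collision warning.

    Clipped segments (>= 5 ms flat at the trace extremes) are reported via a warning
    but detection proceeds.
    """
    fs = trace.sampling_rate
    if fs < 1000:
        raise ValueError("sampling_rate must be >= 1 kHz for spike detection")
    v = trace.voltage
    _warn_clipping(v, fs)
    sos = signal.butter(2, highpass_hz, btype="highpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, v)
    sigma = np.median(np.abs(filt)) / _MAD_TO_SIGMA
    threshold = threshold_sigma * sigma
    above = filt > threshold
    if not above.any() or threshold == 0:
        times = np.empty(0)
    else:
        # [start, stop) runs of suprathreshold samples; one event per run
        run_starts = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8)))) == 1)
        run_stops = np.flatnonzero(np.diff(np.concatenate((above.view(np.int8), [0]))) == -1) + 1
        peaks = np.array(
            [s + int(np.argmax(filt[s:e])) for s, e in zip(run_starts, run_stops)]
        )
        kept: list[int] = []
        n_collisions = 0
        min_gap = min_separation * fs
        for p in peaks:
            if kept and p - kept[-1] < min_gap:
                n_collisions += 1
                continue
            kept.append(int(p))
        if n_collisions:
            logger.warning(
                "detect_spikes: %d peak(s) within the %.1f ms refractory floor collapsed",
                n_collisions,
                min_separation * 1e3,
            )
        times = np.array(kept, dtype=float) / fs
    proto = protocol
    if proto is None:
        d = trace.duration
        proto = SweepProtocol(pre_dark=d, light_on=1e-9, post_dark=1e-9, bin_width=d)
    return SpikeTrain(times=times, protocol=proto, meta=trace.meta)


def _warn_clipping(v: np.ndarray, fs: float) -> None:
    """Warn about saturated/clipped plateaus at the trace extremes (>= 5 ms)."""
    min_run = int(0.005 * fs)
    for extreme in (v.max(), v.min()):
        at = v == extreme
        if at.sum() < min_run:
            continue
        run_starts = np.flatnonzero(np.diff(np.concatenate(([0], at.view(np.int8)))) == 1)
        run_stops = np.flatnonzero(np.diff(np.concatenate((at.view(np.int8), [0]))) == -1) + 1
        segs = [(s / fs, e / fs) for s, e in zip(run_starts, run_stops) if e - s >= min_run]
        if segs:
            logger.warning("detect_spikes: clipped segments at %.2f mV: %s", extreme, segs)


@dataclass
class BinnedCounts:
    """Spike counts aligned to the sweep protocol (half-open bins)."""

    pre: np.ndarray  # counts per 10-s pre-light bin
    light_on: int  # count over [t_on, t_off)
    post: np.ndarray  # counts per 10-s post-stimulus bin

    @property
    def total(self) -> int:
        return int(self.pre.sum() + self.light_on + self.post.sum())


def bin_spike_counts(spikes: SpikeTrain) -> BinnedCounts:
    """Count spikes per protocol-aligned bin.

    Pre-light: ``n_pre_bins`` bins of ``bin_width`` covering [0, t_on); light-on:
    [t_on, t_off); post: five bins of ``bin_width`` from t_off.  All bins half-open.
    """
    p = spikes.protocol
    t = spikes.times
    if t.size and (t[0] < 0 or t[-1] > p.duration):
        raise ValueError("spike times outside the protocol window")
    pre_edges = np.arange(0, p.n_pre_bins + 1) * p.bin_width
    pre, _ = np.histogram(t, bins=pre_edges)
    # np.histogram closes the last bin; fix the boundary spike at exactly t_on
    pre[-1] = int(np.sum((t >= pre_edges[-2]) & (t < p.t_on)))
    light_on = int(np.sum((t >= p.t_on) & (t < p.t_off)))
    post = np.array(
        [
            int(np.sum((t >= p.t_off + i * p.bin_width) & (t < p.t_off + (i + 1) * p.bin_width)))
            for i in range(p.n_post_bins)
        ]
    )
    return BinnedCounts(pre=pre.astype(int), light_on=light_on, post=post)


@dataclass
class FFResult:
    """Per-cell firing-frequency result.

    ``ratio`` is the lights-on/baseline rate ratio (NaN when undefined),
    ``post_bins`` the five 10-s post-stimulus rate ratios, ``baseline_rate`` the
    pre-light rate in Hz; all three are means over this cell's valid sweeps, whose
    per-sweep values are kept alongside.
    """

    ratio: float
    post_bins: np.ndarray
    baseline_rate: float
    sweep_ratios: np.ndarray
    sweep_post_bins: np.ndarray  # shape (n_sweeps, 5)
    sweep_baselines: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ratio)


def _sweep_metrics(spikes: SpikeTrain) -> tuple[float, np.ndarray, float]:
    p = spikes.protocol
    b = bin_spike_counts(spikes)
    baseline_rate = b.pre.sum() / p.pre_dark
    if b.pre.sum() == 0:
        logger.warning(
            "zero baseline spikes (cell %s sweep %s): FF ratio undefined",
            spikes.meta.cell_id,
            spikes.meta.sweep,
        )
        return math.nan, np.full(p.n_post_bins, np.nan), 0.0
    ratio = (b.light_on / p.light_on) / baseline_rate
    post = (b.post / p.bin_width) / baseline_rate
    return ratio, post, baseline_rate


def compute_ff_ratio(spikes: SpikeTrain) -> FFResult:
    """FF ratio for a single sweep: (light-on count/5 s) / (pre-light count/50 s)."""
    ratio, post, baseline = _sweep_metrics(spikes)
    return FFResult(
        ratio=ratio,
        post_bins=post,
        baseline_rate=baseline,
        sweep_ratios=np.array([ratio]),
        sweep_post_bins=post.reshape(1, -1),
        sweep_baselines=np.array([baseline]),
        meta=spikes.meta,
    )


def compute_post_stimulus_profile(spikes: SpikeTrain) -> np.ndarray:
    """Five post-stimulus 10-s rate ratios: (post-bin count/10 s) / baseline rate."""
    _, post, _ = _sweep_metrics(spikes)
    return post


def compute_baseline_ff(spikes: SpikeTrain) -> float:
    """Baseline firing rate in Hz: pre-light spike count / pre-light duration."""
    b = bin_spike_counts(spikes)
    return b.pre.sum() / spikes.protocol.pre_dark


def combine_sweeps(sweeps: list[SpikeTrain]) -> FFResult:
    """Per-cell FF result: mean over this recording's sweeps (undefined sweeps dropped).

    The standard protocol repeats five sweeps per recording; the per-cell value is the
    mean of the per-sweep ratios over the sweeps with a defined ratio.
    """
    if not sweeps:
        raise ValueError("no sweeps")
    metrics = [_sweep_metrics(s) for s in sweeps]
    ratios = np.array([m[0] for m in metrics])
    posts = np.vstack([m[1] for m in metrics])
    baselines = np.array([m[2] for m in metrics])
    ok = ~np.isnan(ratios)
    return FFResult(
        ratio=float(np.mean(ratios[ok])) if ok.any() else math.nan,
        post_bins=np.mean(posts[ok], axis=0) if ok.any() else np.full(posts.shape[1], np.nan),
        baseline_rate=float(np.mean(baselines)),
        sweep_ratios=ratios,
        sweep_post_bins=posts,
        sweep_baselines=baselines,
        meta=sweeps[0].meta,
    )


@dataclass
class GroupSummary:
    """Group mean +/- SEM over cells for one genotype x wavelength condition."""

    genotype: str
    wavelength: int | None
    n: int
    mean: float
    sem: float  # NaN for n = 1
    values: np.ndarray  # raw per-cell values
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n != self.values.size:
            raise ValueError("n must equal the number of per-cell values")


def aggregate_group(
    cells: list[FFResult],
    genotype: str,
    wavelength: int | None = None,
    metric: str = "ratio",
) -> GroupSummary:
    """Aggregate per-cell FF results into a group mean +/- SEM.

    ``metric`` selects ``"ratio"`` (the FF ratio) or ``"baseline"`` (Hz).  Cells with
    an undefined ratio are excluded and counted in ``n_excluded``.
    """
    if metric not in ("ratio", "baseline"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "ratio":
        valid = [c for c in cells if c.defined]
        values = np.array([c.ratio for c in valid])
    else:
        valid = cells
        values = np.array([c.baseline_rate for c in valid])
    n_excluded = len(cells) - len(valid)
    if n_excluded:
        logger.warning("aggregate_group(%s): %d cell(s) excluded (undefined ratio)", genotype, n_excluded)
    if not len(valid):
        raise ValueError(f"no valid cells for group {genotype}")
    n = values.size
    sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n >= 2 else math.nan
    return GroupSummary(
        genotype=genotype,
        wavelength=wavelength,
        n=n,
        mean=float(values.mean()),
        sem=sem,
        values=values,
        n_excluded=n_excluded,
    )


__all__ = [
    "BinnedCounts",
    "FFResult",
    "GroupSummary",
    "HIGHPASS_HZ",
    "REFRACTORY_FLOOR_S",
    "THRESHOLD_SIGMA",
    "aggregate_group",
    "bin_spike_counts",
    "combine_sweeps",
    "compute_baseline_ff",
    "compute_ff_ratio",
    "compute_post_stimulus_profile",
    "detect_spikes",
]
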