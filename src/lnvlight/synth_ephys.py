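"""Synthetic l-LNv voltage-trace generator.

The generator emulates the statistical structure the ephys analysis assumes, not the
biophysics: l-LNvs fire tonically at a genotype-specific baseline rate (~2.4-5.2 Hz), a
5-s light pulse multiplies the rate by a genotype x wavelength fold-change, and after
lights-off the excess rate decays exponentially with a wavelength-dependent time
constant (0 = immediate return, as observed for red light).  Spikes are drawn from an
inhomogeneous Poisson process with a 2 ms absolute refractory period (thinning
construction) and rendered onto a noisy membrane-potential trace as stereotyped 2-ms
biphasic waveforms plus a DC depolarization step during the light.

Determinism: every sweep's spike train and noise derive from a per-(genotype, cell,
sweep) seed computed by :func:`stable_seed` — a SHA-256 hash of the master seed and the
labels — so cohorts are byte-identical across reruns and platforms.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .io_formats import TraceFile, TraceMeta


@dataclass
class SweepProtocol:
    """The light-stimulation sweep: 50 s dark baseline, 5 s light, 95 s dark.

    ``bin_width`` (10 s) frames the analysis: five pre-light bins, the 5-s light-on
    window, and five post-stimulus bins.  The analyzed window is the first
    ``pre_dark + light_on + 5 * bin_width`` = 105 s of the 150-s sweep.
    """

    pre_dark: float = 50.0
    light_on: float = 5.0
    post_dark: float = 95.0
    n_sweeps: int = 5
    bin_width: float = 10.0
    wavelength: int = 450
    intensity: float = 200.0

    def __post_init__(self) -> None:
        if min(self.pre_dark, self.light_on, self.post_dark, self.bin_width) <= 0:
            raise ValueError("all protocol durations must be > 0")
        if self.pre_dark % self.bin_width:
            raise ValueError("bin_width must divide pre_dark")
        if self.light_on > self.bin_width:
            raise ValueError("light_on must fit within one bin")

    @property
    def t_on(self) -> float:
        return self.pre_dark

    @property
    def t_off(self) -> float:
        return self.pre_dark + self.light_on

    @property
    def duration(self) -> float:
        return self.pre_dark + self.light_on + self.post_dark

    @property
    def n_pre_bins(self) -> int:
        return int(round(self.pre_dark / self.bin_width))

    @property
    def n_post_bins(self) -> int:
        return 5

    @property
    def analysis_window(self) -> float:
        """End of the analyzed window (105 s for the default protocol)."""
        return self.t_off + self.n_post_bins * self.bin_width


@dataclass
class EphysGenotypeParams:
    """Generative parameters for one genotype.

    ``fold_change[wavelength]`` is the light-on rate multiplier k (dimensionless, the
    quantity the FF-ratio estimator recovers); ``decay_tau[wavelength]`` the
    post-stimulus persistence time constant in seconds (0 = none).  Waveform and noise
    parameters shape the rendered trace only.
    """

    baseline_rate: float  # Hz
    fold_change: dict[int, float] = field(default_factory=dict)
    decay_tau: dict[int, float] = field(default_factory=dict)
    refractory: float = 0.002  # s, absolute
    spike_amplitude: float = 40.0  # mV above resting
    noise_sd: float = 2.0  # mV
    depolarization_dc: float = 5.0  # mV DC step during light
    resting_mv: float = -45.0

    def __post_init__(self) -> None:
        if not self.baseline_rate > 0:
            raise ValueError("baseline_rate must be > 0")
        if any(k <= 0 for k in self.fold_change.values()):
            raise ValueError("fold changes must be > 0")
        if any(t < 0 for t in self.decay_tau.values()):
            raise ValueError("decay taus must be >= 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.baseline_rate * self.refractory >= 1:
            raise ValueError("baseline_rate * refractory must be < 1")


def stable_seed(master_seed: int, *labels: object) -> int:
    """Deterministic 32-bit child seed from a master seed and string-able labels."""
    key = "|".join([str(int(master_seed)), *map(str, labels)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class RateProfile:
    """Piecewise firing-rate profile sampled on a uniform grid (Hz)."""

    dt: float
    rates: np.ndarray

    @property
    def duration(self) -> float:
        return self.rates.size * self.dt

    def at(self, t: np.ndarray | float) -> np.ndarray:
        idx = np.minimum((np.asarray(t) / self.dt).astype(int), self.rates.size - 1)
        return self.rates[idx]


def simulate_rate_profile(
    params: EphysGenotypeParams, protocol: SweepProtocol, dt: float = 1e-3
) -> RateProfile:
    """Instantaneous firing-rate profile r(t) for one sweep.

    r(t) = r_base before the light, r_base * k during it, and
    r_base * (1 + (k - 1) * exp(-(t - t_off)/tau)) afterwards (tau = 0 meaning an
    immediate return to baseline), so the profile is continuous at lights-off whenever
    tau > 0.
    """
    k = params.fold_change.get(protocol.wavelength, 1.0)
    tau = params.decay_tau.get(protocol.wavelength, 0.0)
    t = np.arange(0.0, protocol.duration, dt)
    r = np.full(t.size, params.baseline_rate)
    during = (t >= protocol.t_on) & (t < protocol.t_off)
    r[during] = params.baseline_rate * k
    after = t >= protocol.t_off
    if tau > 0:
        r[after] = params.baseline_rate * (
            1.0 + (k - 1.0) * np.exp(-(t[after] - protocol.t_off) / tau)
        )
    return RateProfile(dt=dt, rates=r)


@dataclass
class SpikeTrain:
    """Ordered spike times (s from sweep start) with the protocol that frames them."""

    times: np.ndarray
    protocol: SweepProtocol
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (
            np.any(np.diff(self.times) <= 0)
            or self.times[0] < 0
            or self.times[-1] > self.protocol.duration
        ):
            raise ValueError("spike times must be strictly increasing within [0, duration]")


def simulate_spike_train(
    profile: RateProfile,
    refractory: float,
    seed: int,
    protocol: SweepProtocol | None = None,
    meta: TraceMeta | None = None,
) -> SpikeTrain:
    """Inhomogeneous Poisson spike train with absolute refractory period (thinning).

    Candidate events are drawn from a homogeneous Poisson process at the profile's
    maximum rate, thinned by r(t)/r_max, then events closer than ``refractory`` to the
    previously accepted spike are dropped (dead-time renewal construction).  At the
    rates simulated here (2-5 Hz, 2 ms dead time) the stationary rate is
    r / (1 + r * refractory), within half a percent of r.
    """
    rng = np.random.default_rng(seed)
    r_max = float(np.max(profile.rates))
    duration = profile.duration
    if r_max <= 0:
        times = np.empty(0)
    else:
        if refractory > 0 and r_max * refractory >= 1:
            warnings.warn(
                "refractory too long for the requested rate; realized rate saturates",
                stacklevel=2,
            )
        n_cand = rng.poisson(r_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        keep = rng.uniform(0.0, r_max, size=n_cand) < profile.at(cand)
        cand = cand[keep]
        times_list: list[float] = []
        last = -np.inf
        for t in cand:
            if t - last >= refractory:
                times_list.append(t)
                last = t
        times = np.array(times_list)
    if protocol is None:
        # free-standing train: frame it with a trivial protocol of matching duration
        d = max(duration, 1e-9)
        protocol = SweepProtocol(pre_dark=d, light_on=1e-9, post_dark=1e-9, bin_width=d)
    return SpikeTrain(times=times, protocol=protocol, meta=meta or TraceMeta())


def spike_template(sampling_rate: float, amplitude: float) -> tuple[np.ndarray, int]:
    """Stereotyped 2-ms biphasic spike waveform and the index of its peak sample.

    A 1-ms positive half-sine to ``amplitude`` followed by a 1-ms negative half-sine
    afterhyperpolarization at 40% of the amplitude.
    """
    n_half = max(int(round(0.001 * sampling_rate)), 2)
    up = amplitude * np.sin(np.pi * np.arange(n_half) / n_half)
    down = -0.4 * amplitude * np.sin(np.pi * np.arange(n_half) / n_half)
    template = np.concatenate([up, down])
    return template, int(np.argmax(template))


def render_voltage_trace(
    spikes: SpikeTrain,
    params: EphysGenotypeParams,
    protocol: SweepProtocol,
    sampling_rate: float = 10_000.0,
    seed: int = 0,
) -> TraceFile:
    """Render a spike train as a noisy membrane-potential trace.

    Baseline = resting potential + Gaussian noise; a DC depolarization step during the
    light epoch; each spike inserted as the :func:`spike_template` waveform with its
    peak at the spike time (so peak-finding recovers insertion times to within one
    sample).
    """
    if sampling_rate < 1000:
        raise ValueError("sampling_rate below 1 kHz cannot resolve the 2-ms spike waveform")
    if spikes.times.size and spikes.times[-1] > protocol.duration:
        raise ValueError("spike times extend past the protocol duration")
    rng = np.random.default_rng(seed)
    n = int(round(protocol.duration * sampling_rate))
    v = np.full(n, params.resting_mv)
    if params.noise_sd > 0:
        v += rng.normal(0.0, params.noise_sd, size=n)
    i_on = int(round(protocol.t_on * sampling_rate))
    i_off = int(round(protocol.t_off * sampling_rate))
    v[i_on:i_off] += params.depolarization_dc
    template, peak = spike_template(sampling_rate, params.spike_amplitude)
    for t in spikes.times:
        p = int(round(t * sampling_rate))
        lo, hi = p - peak, p - peak + template.size
        tl, th = max(lo, 0), min(hi, n)
        v[tl:th] += template[tl - lo : th - lo]
    return TraceFile(sampling_rate=sampling_rate, voltage=v, meta=spikes.meta)


def iter_ephys_cohort(
    params: EphysGenotypeParams,
    genotype: str,
    n_cells: int,
    protocol: SweepProtocol,
    master_seed: int,
    sampling_rate: float = 10_000.0,
) -> Iterator[tuple[TraceFile, SpikeTrain]]:
    """Yield (trace, ground-truth spike train) pairs for a cohort, sweep by sweep.

    ``n_cells x protocol.n_sweeps`` sweeps are produced lazily so that a full cohort at
    10 kHz never needs to reside in memory at once.  Each cell draws a recording ZT
    hour uniformly from ZT0-16 (the generator has no time-of-day effect, matching the
    absence of a baseline/ZT correlation in the data being emulated).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    profile = simulate_rate_profile(params, protocol)
    for cell in range(1, n_cells + 1):
        zt_rng = np.random.default_rng(stable_seed(master_seed, genotype, cell, "zt"))
        zt_hour = float(np.round(zt_rng.uniform(0.0, 16.0), 2))
        for sweep in range(1, protocol.n_sweeps + 1):
            meta = TraceMeta(
                genotype=genotype,
                wavelength_nm=protocol.wavelength,
                intensity_uw_cm2=protocol.intensity,
                zt_hour=zt_hour,
                cell_id=f"{genotype}-c{cell:03d}",
                sweep=sweep,
            )
            train = simulate_spike_train(
                profile,
                params.refractory,
                stable_seed(master_seed, genotype, cell, sweep, "spikes"),
                protocol=protocol,
                meta=meta,
            )
            trace = render_voltage_trace(
                train,
                params,
                protocol,
                sampling_rate=sampling_rate,
                seed=stable_seed(master_seed, genotype, cell, sweep, "noise"),
            )
            yield trace, train


def simulate_ephys_cohort(
    params: EphysGenotypeParams,
    genotype: str,
    n_cells: int,
    protocol: SweepProtocol,
    master_seed: int,
    sampling_rate: float = 10_000.0,
) -> list[TraceFile]:
    """Materialize a full cohort of trace files (see :func:`iter_ephys_cohort`)."""
    return [
        trace
        for trace, _ in iter_ephys_cohort(
            params, genotype, n_cells, protocol, master_seed, sampling_rate
        )
    ]


__all__ = [
    "EphysGenotypeParams",
    "RateProfile",
    "SpikeTrain",
    "SweepProtocol",
    "iter_ephys_cohort",
    "render_voltage_trace",
    "simulate_ephys_cohort",
    "simulate_rate_profile",
    "simulate_spike_train",
    "spike_template",
    "stable_seed",
]
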