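"""Spike detection, protocol binning, FF ratios and group aggregation."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lnvlight.ephys_analysis import (
    aggregate_group,
    bin_spike_counts,
    combine_sweeps,
    compute_baseline_ff,
    compute_ff_ratio,
    compute_post_stimulus_profile,
    detect_spikes,
)
from lnvlight.io_formats import TraceFile, TraceMeta
from lnvlight.synth_ephys import (
    EphysGenotypeParams,
    SpikeTrain,
    SweepProtocol,
    render_voltage_trace,
    simulate_rate_profile,
    simulate_spike_train,
)


def make_train(times, protocol=None):
    return SpikeTrain(times=np.asarray(times, dtype=float),
                      protocol=protocol or SweepProtocol())


class TestDetectSpikes:
    def test_noise_only_trace_yields_no_events(self):
        rng = np.random.default_rng(0)
        protocol = SweepProtocol(pre_dark=10.0, light_on=1e-9, post_dark=1e-9, bin_width=10.0)
        trace = TraceFile(sampling_rate=2000, voltage=-45 + rng.normal(0, 2.0, 20_000))
        assert detect_spikes(trace, protocol).times.size == 0

    def test_two_spikes_one_ms_apart_collapse_with_warning(self, caplog):
        protocol = SweepProtocol()
        params = EphysGenotypeParams(baseline_rate=1.0, noise_sd=1.0)
        train = make_train([10.0, 10.001, 20.0, 30.0, 40.0, 60.0], protocol)
        trace = render_voltage_trace(train, params, protocol, 10_000, seed=0)
        with caplog.at_level(logging.WARNING, logger="lnvlight.ephys_analysis"):
            detected = detect_spikes(trace, protocol)
        assert detected.times.size == 5  # the 1-ms pair merged
        assert any("refractory floor" in r.message for r in caplog.records)

    def test_dc_light_step_does_not_trigger_events(self):
        protocol = SweepProtocol()
        # generator-default noise and light step: the step transient stays below
        # the robust threshold after high-pass filtering
        params = EphysGenotypeParams(baseline_rate=1.0)
        train = make_train([], protocol)
        trace = render_voltage_trace(train, params, protocol, 2000, seed=1)
        assert detect_spikes(trace, protocol).times.size == 0


class TestBinning:
    def test_empty_train_all_zero(self):
        b = bin_spike_counts(make_train([]))
        assert b.pre.tolist() == [0] * 5 and b.light_on == 0 and b.post.tolist() == [0] * 5

    def test_half_open_boundary_convention(self):
        """A spike at exactly lights-on is light-on; at exactly lights-off, post bin 1."""
        b = bin_spike_counts(make_train([50.0, 55.0]))
        assert b.pre.sum() == 0
        assert b.light_on == 1
        assert b.post.tolist() == [1, 0, 0, 0, 0]

    def test_uniform_one_hz_train(self):
        times = np.arange(0.5, 105.0, 1.0)
        b = bin_spike_counts(make_train(times))
        assert b.pre.tolist() == [10] * 5
        assert b.light_on == 5
        assert b.post.tolist() == [10] * 5

    def test_spikes_outside_protocol_rejected(self):
        protocol = SweepProtocol()
        train = make_train([10.0], protocol)
        train.times = np.array([200.0])  # bypass constructor validation
        with pytest.raises(ValueError, match="outside"):
            bin_spike_counts(train)

    @given(st.integers(0, 2**31 - 1))
    def test_binning_conserves_spikes(self, seed):
        """Sum over all bins equals the spike count in the analyzed [0, 105 s) window."""
        rng = np.random.default_rng(seed)
        times = np.unique(rng.uniform(0, 150.0, size=rng.integers(0, 400)))
        train = make_train(times)
        b = bin_spike_counts(train)
        assert b.total == np.sum(times < 105.0)


class TestFFRatio:
    def test_stationary_periodic_train_ratio_one(self):
        times = np.arange(0.125, 150.0, 0.25)  # exactly 4 Hz throughout
        res = compute_ff_ratio(make_train(times))
        assert res.ratio == pytest.approx(1.0)
        assert res.baseline_rate == pytest.approx(4.0)
        assert np.allclose(compute_post_stimulus_profile(make_train(times)), 1.0)

    def test_rate_convention_worked_example(self):
        """10 pre-light spikes (0.2 Hz) and 3 light-on spikes (0.6 Hz) give ratio 3."""
        pre = np.linspace(1.0, 49.0, 10)
        light = [51.0, 52.0, 53.0]
        res = compute_ff_ratio(make_train(np.concatenate([pre, light])))
        assert res.ratio == pytest.approx(3.0)
        assert res.baseline_rate == pytest.approx(0.2)

    def test_post_profile_worked_example(self):
        """Baseline 0.2 Hz with 4 spikes in post bin 1: post_bins[0] = 2.0."""
        pre = np.linspace(1.0, 49.0, 10)
        post1 = [56.0, 58.0, 60.0, 64.0]
        profile = compute_post_stimulus_profile(make_train(np.concatenate([pre, post1])))
        assert profile[0] == pytest.approx(2.0)
        assert np.allclose(profile[1:], 0.0)

    def test_zero_baseline_is_undefined_not_infinite(self, caplog):
        with caplog.at_level(logging.WARNING, logger="lnvlight.ephys_analysis"):
            res = compute_ff_ratio(make_train([51.0, 52.0]))
        assert math.isnan(res.ratio)
        assert any("undefined" in r.message for r in caplog.records)

    def test_baseline_ff_arithmetic(self):
        times = np.linspace(0.1, 49.9, 210)
        assert compute_baseline_ff(make_train(times)) == pytest.approx(4.2)
        assert compute_baseline_ff(make_train([])) == 0.0


class TestAggregation:
    def _cell(self, ratio):
        """A cell whose five sweeps all have the given FF ratio (0.2 Hz baseline)."""
        pre = np.linspace(1.0, 49.0, 10)
        n_light = int(round(ratio))
        light = 50.5 + np.arange(n_light) * 0.5
        sweeps = [make_train(np.concatenate([pre, light])) for _ in range(5)]
        return combine_sweeps(sweeps)

    def test_single_cell_sem_undefined(self):
        cell = self._cell(2)
        g = aggregate_group([cell], "p12c", 450)
        assert g.n == 1 and math.isnan(g.sem)

    def test_mean_and_sem_worked_example(self):
        cells = [self._cell(r) for r in (1, 2, 3)]
        g = aggregate_group(cells, "p12c", 450)
        assert g.mean == pytest.approx(2.0)
        assert g.sem == pytest.approx(1.0 / np.sqrt(3.0))

    def test_undefined_cells_excluded_and_counted(self):
        bad = combine_sweeps([make_train([51.0])])  # zero baseline: undefined
        cells = [self._cell(2), bad]
        g = aggregate_group(cells, "p12c", 450)
        assert g.n == 1 and g.n_excluded == 1

    def test_empty_group_raises(self):
        bad = combine_sweeps([make_train([51.0])])
        with pytest.raises(ValueError, match="no valid cells"):
            aggregate_group([bad], "p12c", 450)

    def test_per_cell_mean_is_mean_of_sweeps(self, control_params, blue_protocol):
        profile = simulate_rate_profile(control_params, blue_protocol)
        sweeps = [
            simulate_spike_train(profile, 0.002, seed=s, protocol=blue_protocol)
            for s in range(5)
        ]
        cell = combine_sweeps(sweeps)
        assert cell.ratio == pytest.approx(np.nanmean(cell.sweep_ratios))


class TestEstimatorRecovery:
    def test_ff_estimator_unbiased_over_many_cells(self, control_params, blue_protocol):
        """Over 200 simulated cells the mean FF ratio is within 3 SEM of the
        generative fold-change (spike-train level, no rendering)."""
        profile = simulate_rate_profile(control_params, blue_protocol)
        ratios = []
        for cell in range(200):
            sweeps = [
                simulate_spike_train(
                    profile, control_params.refractory, seed=1000 * cell + s,
                    protocol=blue_protocol,
                )
                for s in range(5)
            ]
            ratios.append(combine_sweeps(sweeps).ratio)
        ratios = np.array(ratios)
        sem = ratios.std(ddof=1) / np.sqrt(ratios.size)
        assert abs(ratios.mean() - 1.958) < 3 * sem + 0.02  # + refractory correction slack

    def test_no_persistence_generator_has_flat_post_profile(self):
        """With tau = 0 the cohort post-stimulus profile is consistent with 1."""
        params = EphysGenotypeParams(
            baseline_rate=4.2, fold_change={450: 1.958}, decay_tau={450: 0.0}
        )
        protocol = SweepProtocol(wavelength=450)
        profile = simulate_rate_profile(params, protocol)
        posts = []
        for cell in range(100):
            sweeps = [
                simulate_spike_train(profile, 0.002, seed=977 * cell + s, protocol=protocol)
                for s in range(5)
            ]
            posts.append(combine_sweeps(sweeps).post_bins)
        posts = np.array(posts)
        mean = posts.mean(axis=0)
        sem = posts.std(axis=0, ddof=1) / np.sqrt(posts.shape[0])
        assert np.all(np.abs(mean - 1.0) < 3 * sem)
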