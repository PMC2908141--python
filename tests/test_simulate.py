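"""Synthetic-recording generator: templates, spike trains, rendering, presets."""

import numpy as np
import pytest

import vhmea
from vhmea.preprocess import FilterSpec, filter_trace
from vhmea.simulate import (
    CapacityError,
    InvalidParameterError,
    InvalidTemplateError,
    UnknownConditionError,
    _unit_catalog,
)

QUIET = vhmea.NoiseModel(sd_uv=0.0, drift_amplitude_uv=0.0)


class TestTemplates:
    @pytest.mark.parametrize("polarity,extremum", [("negative", np.min), ("positive", np.max)])
    def test_extremum_matches_requested_peak(self, polarity, extremum):
        tpl = vhmea.make_template(100.0, 1.0, polarity, window=64)
        sign = -1 if polarity == "negative" else 1
        assert extremum(tpl.waveform) == pytest.approx(sign * 100.0)
        assert np.argmax(np.abs(tpl.waveform)) == tpl.extremum_index

    def test_baseline_near_zero(self):
        tpl = vhmea.make_template(100.0, 1.0, "negative")
        assert abs(tpl.waveform[0]) <= 1.0
        assert abs(tpl.waveform[-1]) <= 1.0

    def test_degenerate_amplitude_rejected(self):
        with pytest.raises(InvalidTemplateError):
            vhmea.make_template(0.0, 1.0, "negative")

    def test_too_wide_for_window_rejected(self):
        with pytest.raises(InvalidTemplateError):
            vhmea.make_template(50.0, 3.0, "negative", window=64)

    @pytest.mark.parametrize("width_ms", [0.4, 1.0])
    def test_bandpass_retains_peak(self, width_ms):
        # oracle: run the implemented band-pass itself over the template
        tpl = vhmea.make_template(50.0, width_ms, "negative")
        x = np.zeros(4000)
        x[2000 - 32 : 2000 + 32] += tpl.waveform
        y = filter_trace(x, FilterSpec(), 20_000.0)
        assert np.max(np.abs(y)) >= 0.70 * 50.0

    def test_catalog_templates_keep_alignment_after_filtering(self):
        # the filtered main lobe must dominate the opposing lobe, else
        # the detector's extremum alignment flips between lobes
        for n_units in (4, 5):
            for u in _unit_catalog(0, n_units, np.full(n_units, 1.0), 5.0,
                                   (8.0, 15.0), 2.0, 0.03, 64, 20_000.0):
                x = np.zeros(4000)
                x[2000 - 32 : 2000 + 32] += u.template.waveform
                y = filter_trace(x, FilterSpec(), 20_000.0)
                assert -y.min() / y.max() >= 1.25
                assert abs(int(np.argmin(y)) - (2000 - 32 + u.template.extremum_index)) <= 1


class TestSpikeTrains:
    def test_zero_rate_is_empty(self):
        assert vhmea.simulate_spike_train(0.0, 50.0).size == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            vhmea.simulate_spike_train(-1.0, 50.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_refractory_is_hard(self, seed):
        t = vhmea.simulate_spike_train(80.0, 10.0, refractory_ms=2.0, rng=seed)
        assert np.all(np.diff(t) >= 0.002 - 1e-12)
        assert t[0] >= 0 and t[-1] < 10.0

    def test_mean_count_matches_dead_time_corrected_rate(self):
        # oracle: the generator draws ISIs with mean exactly 1/rate
        # (refractory + exponential with inflated intensity), so the
        # expected count over 50 s is rate * 50 = 304.
        rate, dur = 6.08, 50.0
        counts = [
            len(vhmea.simulate_spike_train(rate, dur, 2.0, rng=seed))
            for seed in range(1000)
        ]
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - rate * dur) <= 3 * se + 1.0  # +1 edge effect


class TestRendering:
    def test_silence_without_units_or_noise(self, geometry, control_preset):
        seg, truth = vhmea.render_recording(
            geometry, control_preset, QUIET, seed=0, duration=1.0, units=[]
        )
        assert not seg.samples.any()
        assert truth.total_spikes() == 0

    def test_noiseless_trace_is_exact_template_superposition(self, geometry, control_preset):
        tpl = vhmea.make_template(50.0, 0.8, "negative")
        unit = vhmea.UnitSpec(electrode=9, template=tpl, rate_hz=5.0, jitter_sd=0.0)
        seg, truth = vhmea.render_recording(
            geometry, control_preset, QUIET, seed=3, duration=2.0, units=[unit]
        )
        expected = np.zeros(seg.n_samples, dtype=np.float64)
        for t in truth.spike_times[(9, 0)]:
            start = int(round(t * seg.fs)) - tpl.extremum_index
            expected[start : start + 64] += tpl.waveform
        np.testing.assert_allclose(seg.samples[9], expected.astype(np.float32), atol=1e-5)
        others = np.delete(np.arange(64), 9)
        assert not seg.samples[others].any()

    def test_noise_sd_matches_request(self, geometry, control_preset):
        seg, _ = vhmea.render_recording(
            geometry, control_preset,
            vhmea.NoiseModel(sd_uv=5.0, drift_amplitude_uv=0.0),
            seed=7, duration=2.0, units=[],
        )
        sds = seg.samples.std(axis=1)
        assert np.all(np.abs(sds - 5.0) <= 0.1)  # within 2 %

    def test_deterministic_under_seed(self, geometry, control_preset):
        a, _ = vhmea.render_recording(geometry, control_preset, vhmea.NoiseModel(),
                                      seed=5, duration=1.0)
        b, _ = vhmea.render_recording(geometry, control_preset, vhmea.NoiseModel(),
                                      seed=5, duration=1.0)
        c, _ = vhmea.render_recording(geometry, control_preset, vhmea.NoiseModel(),
                                      seed=6, duration=1.0)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_planted_truth_matches_recording(self, full_slice):
        truth = full_slice["truth"]
        counts = truth.counts_per_electrode()
        # conservation: per-unit times sum to electrode totals
        assert truth.total_spikes() == sum(counts.values())
        # activity criterion realized by construction on a 50-s segment
        for e in range(64):
            if truth.active[e]:
                assert counts[e] >= 50
            else:
                assert counts.get(e, 0) < 50

    def test_planted_snr_clears_detection_threshold(self, full_slice):
        noise_sd = 5.0
        for tpl in full_slice["truth"].templates.values():
            assert tpl.peak_amplitude_uv / noise_sd >= 8.0

    def test_capacity_error(self, control_preset):
        tiny = vhmea.ArrayGeometry(ventral_horn_mask=tuple(range(4)))
        with pytest.raises(CapacityError):
            vhmea.render_recording(tiny, control_preset, QUIET, seed=0, duration=1.0)


class TestPresets:
    @pytest.mark.parametrize("genotype,drug,n_active,units,rate", [
        ("control", "basal", 15, 5, 6.08),
        ("sma", "basal", 6, 4, 5.48),
        ("control", "serotonin", 25, 7, 10.20),
        ("sma", "serotonin", 11, 5, 6.98),
        ("control", "gaba", 14, 5, 5.74),
        ("sma", "acetylcholine", 6, 4, 5.39),
        ("control", "bicuculline", 16, 5, 5.96),
    ])
    def test_tabulated_condition_values(self, genotype, drug, n_active, units, rate):
        p = vhmea.build_preset(genotype, drug)
        assert p.n_active_electrodes == n_active
        assert p.units_per_active_electrode == units
        assert p.aggregate_rate_hz == pytest.approx(rate)
        assert p.inactive_rate_hz < 1.0

    def test_unknown_condition(self):
        with pytest.raises(UnknownConditionError):
            vhmea.build_preset("control", "caffeine")

    def test_presets_fit_default_mask(self, geometry):
        for gt in ("control", "sma"):
            for drug in ("basal", "serotonin", "gaba", "acetylcholine", "bicuculline"):
                p = vhmea.build_preset(gt, drug)
                assert p.n_active_electrodes <= len(geometry.ventral_horn_mask)
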