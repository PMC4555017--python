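"""Generative model: spike statistics, quantization, GPIO, determinism."""

import numpy as np
import pytest

from drivedaq.analysis import detect_spikes, rms
from drivedaq.codec import read_session
from drivedaq.simulate import (
    SimConfig,
    biphasic_waveform,
    dequantize,
    generate_session,
    generate_spike_times,
    gpio_words,
    named_gpio_pattern,
    quantize,
    render_unit,
    session_ground_truth,
    site_positions,
)

from conftest import session_bytes


class TestSpikeTimes:
    def test_zero_rate_gives_empty_train(self):
        assert generate_spike_times(0.0, 100.0, seed=1).size == 0

    def test_count_within_poisson_band(self):
        # rate 10 Hz over 100 s: mean 1000, 4-sigma band ~ +/- 126
        n = generate_spike_times(10.0, 100.0, seed=42).size
        assert abs(n - 1000) < 4 * np.sqrt(1000)

    def test_identical_seeds_identical_trains(self):
        a = generate_spike_times(7.0, 30.0, seed=9)
        b = generate_spike_times(7.0, 30.0, seed=9)
        assert np.array_equal(a, b)

    def test_times_sorted_within_duration(self):
        t = generate_spike_times(20.0, 10.0, seed=3)
        assert np.all(np.diff(t) >= 0) and t[0] >= 0 and t[-1] <= 10.0


class TestSpatialModel:
    def test_amplitude_decays_with_distance(self):
        sites = site_positions(128)
        unit = sites[40] + 0.1
        amps = render_unit(sites, unit, peak_uv=150.0, spatial_decay_um=25.0)
        d = np.linalg.norm(sites - unit, axis=1)
        order = np.argsort(d)
        assert np.all(np.diff(amps[order]) <= 1e-12)

    def test_closed_form_at_zero_and_one_decay_length(self):
        sites = np.array([[0.0, 0.0], [25.0, 0.0]])
        amps = render_unit(sites, np.array([0.0, 0.0]), 100.0, 25.0)
        assert amps[0] == pytest.approx(100.0)
        assert amps[1] == pytest.approx(100.0 / np.e)

    def test_close_packed_footprint_spans_many_sites(self):
        # 4 x 10 patch at 11.5 um pitch around the unit: every site sees signal,
        # several above half peak when decay >= pitch
        sites = site_positions(40, pitch_um=11.5, n_columns=4)
        unit = (sites[18] + sites[22]) / 2  # midway between two adjacent rows
        amps = render_unit(sites, unit, 150.0, spatial_decay_um=11.5)
        assert np.all(amps > 0)
        assert np.count_nonzero(amps > 75.0) >= 2


class TestQuantize:
    @pytest.mark.parametrize(
        "uv,code",
        [(0.0, 32768), (0.195, 32769), (-0.195, 32767), (1e9, 65535), (-1e9, 0)],
    )
    def test_offset_and_saturation(self, uv, code):
        assert quantize(uv, lsb_uv=0.195) == code

    def test_dequantize_inverts_within_half_lsb(self, rng):
        uv = rng.uniform(-1000, 1000, 100)
        back = dequantize(quantize(uv, 0.195), 0.195)
        assert np.all(np.abs(back - uv) <= 0.195 / 2 + 1e-9)


class TestGpio:
    def test_constant_pattern_fills_all_words(self):
        w = gpio_words(64, named_gpio_pattern("constant:0xFFFF"))
        assert np.all(w == 0xFFFF)
        assert np.all(gpio_words(64, None) == 0)

    def test_state_held_for_15_samples(self):
        # 1 kHz square wave on pin 0: the bit toggles only on alternate
        # 2 kHz ticks, i.e. every 15 acquisition samples
        w = gpio_words(150, named_gpio_pattern("square:0:1000"))
        bit = w & 1
        for tick in range(10):
            seg = bit[tick * 15 : (tick + 1) * 15]
            assert np.all(seg == seg[0])
        assert np.array_equal(bit[::15] , (np.arange(10) % 2))

    def test_counter_pattern_advances_at_2khz(self):
        w = gpio_words(45, named_gpio_pattern("counter"))
        assert w[0] == 0 and w[15] == 1 and w[30] == 2


class TestSessionGeneration:
    def test_byte_determinism_per_seed(self):
        cfg = dict(n_chips=2, n_units=3, duration_samples=300, seed=17)
        assert session_bytes(SimConfig(**cfg)) == session_bytes(SimConfig(**cfg))
        assert session_bytes(SimConfig(**cfg)) != session_bytes(SimConfig(**{**cfg, "seed": 18}))

    def test_noise_only_rms_matches_configuration(self):
        # noise floor recovery at 1e5 samples; 3.9 uV RMS configured
        cfg = SimConfig(n_chips=1, n_units=0, duration_samples=100_000, seed=23)
        samples = generate_session(cfg)
        ch0 = np.fromiter(
            (s.neural[0] for s in samples), dtype=np.uint16, count=cfg.duration_samples
        )
        measured = rms(dequantize(ch0, cfg.lsb_uv))
        assert abs(measured - 3.9) / 3.9 < 0.05

    def test_high_snr_spike_count_recovery(self):
        # one loud unit on a quiet array: threshold detection at 4x noise RMS
        # recovers the generated spike count
        cfg = SimConfig(
            n_chips=1,
            n_units=1,
            duration_samples=60_000,
            firing_rate_hz=10.0,
            spike_peak_uv=250.0,
            spatial_decay_um=1000.0,  # near-uniform: every site sees the unit
            noise_rms_uv=3.9,
            seed=31,
        )
        data = session_bytes(cfg)
        samples = list(read_session(data))
        trace = dequantize(
            np.array([s.neural[0] for s in samples], dtype=np.uint16), cfg.lsb_uv
        )
        detected = detect_spikes(trace, threshold_uv=4 * 3.9, refractory_ms=1.5)
        generated = sum(u.spike_samples.size for u in session_ground_truth(cfg))
        # near-exact recovery of the generated train, with Poisson-scale slack
        # for coincident events and edge effects
        assert generated > 0
        assert abs(detected.size - generated) <= max(2, 0.1 * generated)

    def test_dead_chips_zero_filled_and_masked(self):
        cfg = SimConfig(n_chips=4, dead_chips={2}, n_units=0, duration_samples=16, seed=2)
        for s in generate_session(cfg):
            assert s.metadata.chip_live == 0b1011
            assert not s.neural[64:96].any()  # chip 2 channels
            assert s.neural[0:64].any()  # live chips carry noise
            assert not s.neural[128:].any()  # absent chips 4..31

    def test_index_rollover_at_2_32(self):
        cfg = SimConfig(
            n_chips=1, n_units=0, duration_samples=5, seed=1, start_index=2**32 - 2
        )
        idx = [s.metadata.sample_index for s in generate_session(cfg)]
        assert idx == [2**32 - 2, 2**32 - 1, 0, 1, 2]

    def test_gpio_word_lands_in_designated_aux_slot(self):
        cfg = SimConfig(
            n_chips=1,
            n_units=0,
            duration_samples=30,
            seed=1,
            gpio_pattern=named_gpio_pattern("counter"),
            gpio_aux_slot=1,
        )
        samples = list(generate_session(cfg))
        assert samples[0].aux[1] == 0 and samples[16].aux[1] == 1
        assert samples[0].aux[0] == cfg.aux_fill and samples[0].aux[2] == cfg.aux_fill

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_chips=33)
        with pytest.raises(ValueError):
            SimConfig(n_chips=4, dead_chips={7})
        with pytest.raises(ValueError):
            SimConfig(duration_samples=0)
        with pytest.raises(ValueError):
            SimConfig(noise_rms_uv=-1)


class TestWaveform:
    def test_template_is_unit_negative_biphasic(self):
        w = biphasic_waveform()
        assert w.min() == pytest.approx(-1.0)
        assert w.max() > 0.05  # repolarization lobe present
        assert np.argmin(w) < np.argmax(w)
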