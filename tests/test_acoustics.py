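"""Acoustic feature extraction: f0 tracking, spectral statistics,
modulation rates, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dovekie import acoustics as ac
from dovekie import synth
from dovekie.acoustics import F0Contour, FeatureUndefinedError

from conftest import FS, harmonic_stack


class TestTrackF0:
    def test_pure_tone_all_voiced_and_accurate(self, tone):
        c = ac.track_f0(tone, FS)
        assert c.voiced.all()
        assert np.abs(c.f0[c.voiced] - 700).max() < 1.0

    def test_white_noise_mostly_unvoiced(self):
        rng = np.random.default_rng(0)
        unvoiced_fracs = []
        for _ in range(5):
            x = rng.normal(size=int(0.5 * FS))
            c = ac.track_f0(x, FS)
            unvoiced_fracs.append(1 - c.voiced.mean())
        assert np.mean(unvoiced_fracs) >= 0.90

    def test_too_short_waveform_rejected(self):
        with pytest.raises(ValueError):
            ac.track_f0(np.zeros(100), FS)

    def test_silence_returns_unvoiced_contour(self):
        c = ac.track_f0(np.zeros(int(0.2 * FS)), FS)
        assert not c.voiced.any()

    @pytest.mark.parametrize("f0", np.linspace(400, 1400, 11))
    def test_harmonic_stack_sweep_under_one_percent(self, f0):
        """Noiseless harmonic stacks over the species' f0 band are
        recovered to < 1% relative error."""
        stats = ac.f0_statistics(ac.track_f0(harmonic_stack(f0), FS))
        assert abs(stats["f0_mean"] - f0) / f0 < 0.01

    def test_clucking_corpus_grand_mean_matches_published(self, specs):
        vals = []
        for s in range(30):
            wav, _ = synth.synthesize_call(specs["clucking"], seed=7000 + s)
            fv = ac.extract_features(wav, FS)
            vals.append(fv.f0_mean)
        se = 80.18 / np.sqrt(30)
        # tracker bias on fast arched contours is ~20 Hz, well inside 3 SE
        assert abs(np.mean(vals) - 751.51) < 3 * se


class TestF0Statistics:
    def test_constant_contour(self):
        t = np.arange(10) * 0.01
        c = F0Contour(t, np.full(10, 700.0), np.ones(10, bool))
        s = ac.f0_statistics(c)
        assert s["f0_range"] == 0
        assert s["f0_abs_slope"] == 0
        assert s["f0_var"] == 0
        assert s["f0_mean"] == 700

    def test_linear_ramp_closed_form(self):
        n = 101
        t = np.linspace(0, 1, n)
        f = np.linspace(600, 900, n)
        s = ac.f0_statistics(F0Contour(t, f, np.ones(n, bool)))
        assert s["f0_mean"] == pytest.approx(750)
        assert s["f0_abs_slope"] == pytest.approx(300)
        assert s["f0_var"] == pytest.approx(300)
        assert s["f0_start"] == 600 and s["f0_end"] == 900

    def test_triangle_hand_computation(self):
        c = F0Contour([0.0, 0.1, 0.2], [700.0, 800.0, 700.0],
                      [True, True, True])
        s = ac.f0_statistics(c)
        assert s["f0_abs_slope"] == pytest.approx(1000)
        assert s["f0_range"] == pytest.approx(100)
        assert s["f0_var"] == pytest.approx(1000)  # 200 Hz over 0.2 s

    def test_too_few_voiced_frames(self):
        c = F0Contour([0.0, 0.01], [700.0, np.nan], [True, False])
        with pytest.raises(FeatureUndefinedError):
            ac.f0_statistics(c)


class TestSpectralQuartiles:
    def test_single_tone_quartiles_collapse(self, tone):
        q = ac.spectral_quartiles(tone, FS)
        for key in ("q25", "q50", "q75", "spectral_cog"):
            assert q[key] == pytest.approx(700, abs=50)

    def test_two_equal_tones_discrete_masses(self):
        t = np.arange(FS) / FS
        x = np.sin(2 * np.pi * 1000 * t) + np.sin(2 * np.pi * 3000 * t)
        q = ac.spectral_quartiles(x, FS)
        assert q["spectral_cog"] == pytest.approx(2000, abs=60)
        assert q["q25"] == pytest.approx(1000, abs=60)
        assert q["q75"] == pytest.approx(3000, abs=60)

    def test_white_noise_flat_spectrum(self):
        x = np.random.default_rng(1).normal(size=4 * FS)
        q = ac.spectral_quartiles(x, FS)
        assert q["q50"] == pytest.approx(12_000, rel=0.03)
        assert q["spectral_cog"] == pytest.approx(12_000, rel=0.03)

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError):
            ac.spectral_quartiles(np.zeros(1000), FS)


class TestModulationRates:
    def test_am_ten_hertz(self):
        t = np.arange(FS) / FS
        x = np.sin(2 * np.pi * 700 * t) * (
            1 - 0.25 * (1 + np.cos(2 * np.pi * 10 * t)))
        assert ac.am_rate(x, FS) == pytest.approx(10, abs=1)

    def test_clucking_am_rate_recovery_within_ten_percent(self, specs):
        """Fixed-rate (26.28 / s, SD 0) clucking corpus: extracted grand
        mean within 10% of the modulation rate (the residual deviation is
        integer peak-count quantization on ~90 ms calls)."""
        from dataclasses import replace
        spec = replace(specs["clucking"], am_rate_dist=(26.28, 0.0))
        rates = [ac.extract_features(
                     *synth.synthesize_call(spec, seed=300 + s)[:1], FS).am_rate
                 for s in range(30)]
        assert np.mean(rates) == pytest.approx(26.28, rel=0.10)

    def test_unmodulated_tone_rate_zero(self, tone):
        assert ac.am_rate(tone, FS) == 0.0

    def test_short_call_guard(self):
        with pytest.raises(ValueError):
            ac.am_rate(np.ones(100), FS)

    def test_fm_vibrato_five_hertz(self):
        # 5 Hz vibrato: 2 derivative sign changes per cycle -> 10 / s
        t = np.linspace(0, 1, 101)
        f = 800 + 50 * np.sin(2 * np.pi * 5 * t)
        c = F0Contour(t, f, np.ones(101, bool))
        assert ac.fm_rate(c) == pytest.approx(10, abs=1)

    def test_fm_monotone_and_constant_are_zero(self):
        t = np.linspace(0, 1, 51)
        ramp = F0Contour(t, np.linspace(600, 900, 51), np.ones(51, bool))
        const = F0Contour(t, np.full(51, 700.0), np.ones(51, bool))
        assert ac.fm_rate(ramp) == 0.0
        assert ac.fm_rate(const) == 0.0


class TestExtractFeatures:
    def test_zero_variance_flat_call_recovery(self):
        from test_synth import flat_spec
        wav, _ = synth.synthesize_call(flat_spec(), seed=0)
        fv = ac.extract_features(wav, FS)
        assert fv.f0_mean == pytest.approx(750, abs=7.5)
        assert fv.duration == pytest.approx(0.5, abs=0.01)

    def test_classic_duration_recovery(self, specs):
        durs = [ac.extract_features(
                    *synth.synthesize_call(specs["classic"], seed=4000 + s)[:1],
                    FS).duration
                for s in range(30)]
        se = 0.44 / np.sqrt(30)
        assert abs(np.mean(durs) - 2.74) < 3 * se

    def test_full_corpus_no_missing_rows(self, specs):
        corpus = synth.synthesize_corpus(specs, 3, seed=77)
        feats = [ac.extract_features(c.waveform, c.sample_rate,
                                     call_id=c.call_id, call_type=c.call_type)
                 for c in corpus.calls]
        assert len(feats) == 24
        for fv in feats:
            assert all(np.isfinite(v) for v in fv.as_dict().values())

    def test_gain_invariance(self, specs):
        """+-20 dB gain changes no feature (all measures normalized)."""
        wav, _ = synth.synthesize_call(specs["short"], seed=11)
        base = ac.extract_features(wav, FS).as_dict()
        for gain_db in (-20, 20):
            scaled = ac.extract_features(wav * 10 ** (gain_db / 20), FS).as_dict()
            for key, val in base.items():
                assert scaled[key] == pytest.approx(val, rel=1e-6), key

    def test_error_carries_call_id(self):
        with pytest.raises(ValueError, match="my_call"):
            ac.extract_features(np.zeros(2000), FS, call_id="my_call")

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        f0=st.floats(500, 1100),
        rng_frac=st.floats(0, 0.3),
        dur=st.floats(0.08, 0.4),
        shape=st.sampled_from(["flat", "rise", "fall", "arch", "trill"]),
    )
    def test_feature_vector_orderings_hold(self, f0, rng_frac, dur, shape):
        """min <= mean <= max, quartile ordering, positive duration and
        non-negative rates hold for arbitrary synthesis specs (enforced by
        the AcousticFeatureVector constructor)."""
        spec = synth.SynthesisSpec(
            call_type="single", f0_mean_dist=(f0, 0.0),
            f0_range_dist=(f0 * rng_frac, 0.0), duration_dist=(dur, 0.0),
            am_rate_dist=(20.0, 0.0), fm_rate_dist=(5.0, 0.0),
            contour_shape=shape, noise_snr=25.0)
        wav, _ = synth.synthesize_call(spec, seed=123)
        fv = ac.extract_features(wav, FS)
        assert fv.f0_min <= fv.f0_mean <= fv.f0_max
        assert fv.q25 <= fv.q50 <= fv.q75
        assert fv.duration > 0 and fv.am_rate >= 0 and fv.fm_rate >= 0
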