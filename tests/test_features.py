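"""Frequency COG, jump/turn detectors, per-syllable and per-song parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from usvsong import (
    Song,
    SynthesisConfig,
    count_songs,
    detect_jumps,
    detect_turns,
    frequency_cog,
    saturation_bootstrap,
    song_features,
    syllable_features,
    synth_song,
    synth_syllable,
)
from usvsong.profiles import TYPE13
from usvsong.segmentation import group_songs, segment_syllables

from conftest import make_trace


class TestFrequencyCog:
    def test_equal_amplitudes_give_plain_mean(self):
        assert frequency_cog(make_trace([70, 80, 90])) == pytest.approx(80.0)

    def test_amplitude_weighting(self):
        tr = make_trace([60, 100], amps=[1, 3])
        assert frequency_cog(tr) == pytest.approx(90.0)

    def test_single_sample_identity(self):
        assert frequency_cog(make_trace([75], amps=[0.3])) == pytest.approx(75.0)

    def test_all_zero_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="zero amplitudes"):
            frequency_cog(make_trace([80, 81], amps=[0, 0]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(20, 120), min_size=2, max_size=30), st.data())
    def test_cog_bounded_by_min_max_and_scale_invariant(self, freqs, data):
        amps = data.draw(st.lists(st.floats(0.01, 10), min_size=len(freqs),
                                  max_size=len(freqs)))
        tr = make_trace(freqs, amps=amps)
        cog = frequency_cog(tr)
        assert min(freqs) - 1e-9 <= cog <= max(freqs) + 1e-9
        scaled = make_trace(freqs, amps=np.array(amps) * 7.3)
        assert frequency_cog(scaled) == pytest.approx(cog)


class TestJumps:
    def test_single_up_step_early(self):
        f = [80.0] * 30 + [105.0] * 70  # +25 step at 30% of the contour
        ev = detect_jumps(make_trace(f))
        assert len(ev) == 1
        assert ev[0].direction == "up" and ev[0].magnitude >= 25
        assert ev[0].position < 0.5

    def test_smooth_ramp_no_jump(self):
        f = 60 + 0.05 * 0.5 * np.arange(200)  # 0.05 kHz/ms
        assert detect_jumps(make_trace(f)) == []

    def test_up_then_down_two_events(self):
        f = [80.0] * 20 + [105.0] * 20 + [80.0] * 20
        ev = detect_jumps(make_trace(f))
        assert [e.direction for e in ev] == ["up", "down"]

    def test_translation_invariance(self):
        f = np.array([80.0] * 10 + [105.0] * 10)
        base = detect_jumps(make_trace(f))
        shifted = detect_jumps(make_trace(f + 11.0, t0=321.0))
        assert [(e.direction, e.magnitude) for e in base] == \
               [(e.direction, e.magnitude) for e in shifted]

    def test_accumulated_step_within_window_counts(self):
        # 3 consecutive 7-kHz steps: 21 kHz within 3 steps -> one jump
        f = [80.0] * 10 + [87.0, 94.0] + [101.0] * 10
        ev = detect_jumps(make_trace(f))
        assert len(ev) == 1 and ev[0].magnitude == pytest.approx(21.0)

    def test_slow_accumulation_beyond_window_does_not_count(self):
        # 21 kHz over 6 steps, max 3-step sum 10.5 < 20
        f = np.concatenate([np.full(10, 80.0), 80 + 3.5 * np.arange(1, 7),
                            np.full(10, 101.0)])
        assert detect_jumps(make_trace(f)) == []


class TestTurns:
    def test_v_contour_one_down_up(self):
        f = np.concatenate([np.linspace(81, 80, 5), np.linspace(80.25, 81, 4)])
        ev = detect_turns(make_trace(f))  # falls 1 kHz in 2 ms, rises 1 kHz in 2 ms
        assert len(ev) == 1 and ev[0].shape == "down-up"

    def test_monotone_ramp_no_turn(self):
        f = 60 + 0.3 * 0.5 * np.arange(100)
        assert detect_turns(make_trace(f)) == []

    def test_w_contour_three_reversals(self):
        leg = np.linspace(0, 1.5, 4)  # 1.5 kHz in 1.5 ms per leg
        f = np.concatenate([80 - leg, 78.5 + leg[1:], 80 - leg[1:], 78.5 + leg[1:]])
        ev = detect_turns(make_trace(f))
        assert [e.shape for e in ev] == ["down-up", "up-down", "down-up"]

    def test_shallow_reversal_ignored(self):
        f = np.concatenate([np.linspace(80.5, 80, 5), np.linspace(80.1, 80.5, 5)])
        assert detect_turns(make_trace(f)) == []  # legs only 0.5 kHz

    def test_jump_steps_masked_out(self):
        # a +25 jump followed immediately by a -25 jump is not a turn
        f = [80.0] * 10 + [105.0] + [80.0] * 10
        tr = make_trace(f)
        assert len(detect_jumps(tr)) == 2
        assert detect_turns(tr) == []


class TestSyllableFeatures:
    def test_flat_contour(self):
        ft = syllable_features(make_trace([80.0] * 101))  # 50 ms
        assert ft.duration == pytest.approx(50.0)
        assert ft.freq_slope == pytest.approx(0.0)
        assert ft.freq_band == 0.0
        assert ft.freq_cog == pytest.approx(80.0)
        assert ft.n_jumps == ft.n_turns == 0

    def test_linear_ramp_slope_and_band(self):
        ft = syllable_features(make_trace(np.linspace(60, 100, 81)))  # 40 ms
        assert ft.freq_slope == pytest.approx(1.0)
        assert ft.freq_band == pytest.approx(40.0)
        assert ft.freq_sta == pytest.approx(60.0)
        assert ft.freq_min == pytest.approx(60.0)

    def test_cog_between_min_and_max_on_synthetic_corpus(self, gerf, quiet_cfg):
        rng = np.random.default_rng(7)
        for i in range(30):
            tr = synth_syllable(TYPE13[i % 13], gerf, quiet_cfg, rng)
            ft = syllable_features(tr)
            assert ft.freq_min - 1e-9 <= ft.freq_cog <= ft.freq_min + ft.freq_band + 1e-9

    def test_noise_free_templates_have_expected_event_counts(self, gerf, quiet_cfg):
        expected = {"SFL": (0, 0), "SUP": (0, 0), "SDN": (0, 0),
                    "TDU": (0, 1), "TUD": (0, 1),
                    "JEU": (1, 0), "JLD": (1, 0), "JUD": (2, 0), "JDU": (2, 0)}
        rng = np.random.default_rng(13)
        for t, (nj, nt) in expected.items():
            for _ in range(10):
                ft = syllable_features(synth_syllable(t, gerf, quiet_cfg, rng))
                assert (ft.n_jumps, ft.n_turns) == (nj, nt), t
        for _ in range(10):
            ft = syllable_features(synth_syllable("TRS", gerf, quiet_cfg, rng))
            assert ft.n_jumps == 0 and ft.n_turns >= 2
            ft = syllable_features(synth_syllable("JPS", gerf, quiet_cfg, rng))
            assert ft.n_jumps > 2

    def test_group_mean_duration_recovered(self, gerf, quiet_cfg):
        rng = np.random.default_rng(17)
        durs = [synth_syllable("SUP", gerf, quiet_cfg, rng).duration_ms
                for _ in range(1000)]
        se = gerf.param("duration").sd / np.sqrt(1000)
        assert abs(np.mean(durs) - 69.4) < 3 * se

    def test_group_mean_start_frequency_recovered(self, profiles, quiet_cfg):
        prof = profiles["GER/m"]
        rng = np.random.default_rng(19)
        f0s = [syllable_features(synth_syllable("SUP", prof, quiet_cfg, rng)).freq_sta
               for _ in range(1000)]
        se = prof.param("freq_sta").sd / np.sqrt(1000)
        assert abs(np.mean(f0s) - 80.1) < 3 * se


class TestSongFeatures:
    def test_five_syllables_spanning_250ms(self):
        # 5 syllables of 5 ms, separated by 56.25 ms, spanning 250 ms in total
        traces = [make_trace([80] * 11, t0=61.25 * i) for i in range(5)]
        songs = group_songs(segment_syllables(traces))
        assert songs[0].n_syllables == 5
        dur, rate = song_features(songs[0])
        assert dur == pytest.approx(250.0)
        assert rate == pytest.approx(20.0)

    def test_one_syllable_song(self):
        songs = group_songs(segment_syllables([make_trace([80] * 101)]))
        dur, rate = song_features(songs[0])
        assert (dur, rate) == (pytest.approx(50.0), pytest.approx(20.0))

    def test_fra_m_corpus_mean_rate(self, profiles, quiet_cfg):
        prof = profiles["FRA/m"]
        rng = np.random.default_rng(23)
        rates = [song_features(synth_song(prof, None, quiet_cfg, rng))[1]
                 for _ in range(500)]
        se = prof.param("syllable_rate").sd / np.sqrt(500)
        assert abs(np.mean(rates) - 31.8) < 3 * se


class TestCountSongs:
    def _song(self, ind, ctx, night, t0):
        syl = segment_syllables([make_trace([80] * 11, t0=t0)])[0]
        syl.individual, syl.context, syl.night = ind, ctx, night
        return Song(syllables=[syl], song_id=f"{ind}-{t0}")

    def test_non_singers_retained_with_zero(self):
        songs = [self._song("m1", "DiffSex", 1, 0.0)]
        df = count_songs(songs, individuals=["m1", "m2"])
        assert df.set_index("individual").loc["m2", "n_songs"] == 0

    def test_sum_over_contexts_equals_total(self):
        songs = [self._song("m1", c, 1, 1000.0 * i)
                 for i, c in enumerate(["DiffSex", "DiffSex", "SameSex", "DiffPop"])]
        df = count_songs(songs)
        assert df["n_songs"].sum() == 4
        assert df.groupby("individual")["n_songs"].sum().loc["m1"] == 4

    def test_missing_metadata_rejected(self):
        syl = segment_syllables([make_trace([80] * 11)])[0]
        with pytest.raises(ValueError, match="metadata"):
            count_songs([Song(syllables=[syl], song_id="s")])


class TestSaturationBootstrap:
    def _songs(self, values):
        out = []
        for i, v in enumerate(values):
            n = max(int(round(v / 0.5)) + 1, 2)
            tr = make_trace([80] * n, t0=2000.0 * i)
            out.append(group_songs(segment_syllables([tr]))[0])
        return out

    def test_identical_songs_zero_variance(self):
        songs = {"a": self._songs([50.0] * 36)}
        df = saturation_bootstrap(songs, lambda s: s.duration_ms,
                                  rng=np.random.default_rng(0), n_boot=20)
        assert (df["mean_variance"] == 0).all()

    def test_iid_parameters_flat_curve_flags_plateau(self):
        rng = np.random.default_rng(1)
        songs = {f"i{j}": self._songs(rng.uniform(30, 90, size=36)) for j in range(4)}
        df = saturation_bootstrap(songs, lambda s: s.duration_ms,
                                  rng=np.random.default_rng(2), n_boot=50)
        assert df.attrs["plateau_k"] is not None

    def test_no_eligible_individual_raises(self):
        songs = {"a": self._songs([50.0] * 5)}
        with pytest.raises(ValueError, match="no individual"):
            saturation_bootstrap(songs, lambda s: s.duration_ms,
                                 rng=np.random.default_rng(0))
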