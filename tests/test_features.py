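"""Windowed metrics: filter contracts, closed forms, and a naive-loop oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shiftsense import features, fusion, synthgen
from shiftsense.features import FeatureConfig, EdaDecomposition
from shiftsense.session_io import EDA_COLUMNS, METRIC_COLUMNS, RawStream

START = 1_700_000_000.0


def stream(values, rate=4.0, start=START):
    return RawStream(start, rate, np.asarray(values, dtype=float))


class TestDecomposeEda:
    def test_constant_preserved_exactly(self):
        d = features.decompose_eda(stream(np.full(2000, 1.234)))
        np.testing.assert_allclose(d.baseline.values, 1.234, atol=1e-9)
        np.testing.assert_allclose(d.bandpass.values, 0.0, atol=1e-9)

    def test_linear_ramp_reproduced_away_from_edges(self):
        t = np.arange(2000) / 4.0
        d = features.decompose_eda(stream(1.0 + 0.002 * t))
        interior = slice(200, 1800)
        np.testing.assert_allclose(
            d.baseline.values[interior], (1.0 + 0.002 * t)[interior], atol=1e-9
        )

    def test_band_split_of_slow_fluctuation(self):
        """A 0.2 Hz sine belongs to the fluctuation band: most of its power
        reaches the bandpass signal, little stays in the baseline."""
        t = np.arange(0, 600, 0.25)
        d = features.decompose_eda(stream(2.0 + np.sin(2 * np.pi * 0.2 * t)))
        mid = slice(400, 2000)
        rms_unit = 1.0 / math.sqrt(2)
        bandpass_gain = d.bandpass.values[mid].std() / rms_unit
        baseline_gain = (d.baseline.values[mid] - 2.0).std() / rms_unit
        assert bandpass_gain >= 0.7
        assert baseline_gain <= 0.3

    def test_baseline_plus_residual_identity(self):
        rng = np.random.default_rng(2)
        x = 1.0 + 0.1 * rng.standard_normal(1500)
        d = features.decompose_eda(stream(x))
        residual = x - d.baseline.values
        assert d.baseline.values.shape == x.shape
        # the second filter smooths the residual, it does not re-scale it
        assert abs(d.bandpass.values.mean() - residual.mean()) < 1e-3

    def test_short_stream_rejected(self):
        with pytest.raises(ValueError, match="length"):
            features.decompose_eda(stream(np.ones(50)))


class TestActivity:
    def test_magnitude_is_euclidean_norm(self):
        acc = stream(np.tile([3.0, 4.0, 0.0], (64, 1)), rate=32.0)
        np.testing.assert_allclose(features.acc_magnitude(acc).values, 5.0)

    def test_constant_gravity_filtered_to_zero(self):
        acc = stream(np.tile([0.0, 0.0, 1.0], (3840, 1)), rate=32.0)
        out = features.activity_signal(acc)
        assert np.abs(out.values[320:-320]).max() < 1e-9

    def test_passband_gain_near_unity_at_1hz(self):
        t = np.arange(0, 120, 1 / 32)
        acc = np.zeros((len(t), 3))
        acc[:, 2] = 1.0 + 0.5 * np.sin(2 * np.pi * 1.0 * t)
        out = features.activity_signal(stream(acc, rate=32.0))
        gain = out.values[1000:2800].std() * math.sqrt(2) / 0.5
        assert gain == pytest.approx(1.0, rel=0.05)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            features.activity_signal(stream(np.ones(100), rate=32.0))

    def test_counts_zero_signal(self):
        out = features.activity_counts(stream(np.zeros(320), rate=32.0))
        np.testing.assert_array_equal(out.values, 0.0)
        assert out.sample_rate == 1.0

    def test_counts_constant_epoch(self):
        out = features.activity_counts(stream(np.full(32, -0.5), rate=32.0))
        assert out.values[0] == pytest.approx(16.0)

    def test_counts_match_bruteforce(self, rng):
        x = rng.standard_normal(32 * 17 + 5)
        out = features.activity_counts(stream(x, rate=32.0))
        expected = [np.abs(x[32 * k: 32 * (k + 1)]).sum() for k in range(17)]
        np.testing.assert_allclose(out.values, expected, atol=1e-12)


class TestTimeMetrics:
    def test_first_window(self):
        ts, el, mid = features.window_time_metrics(START, 3)
        assert ts[0] == START and el[0] == 0.0

    def test_elapsed_from_midnight_at_midnight_start(self):
        midnight = 86400.0 * 20000
        ts, el, frm = features.window_time_metrics(midnight, 4)
        assert frm[3] == pytest.approx(60.0)

    def test_window_crossing_midnight_resets(self):
        midnight = 86400.0 * 20000
        start = midnight - 30.0  # second window starts 10 s before midnight
        _, _, frm = features.window_time_metrics(start, 3)
        assert frm[0] == pytest.approx(86370.0)
        assert frm[2] == pytest.approx(10.0)  # reset below 20 after midnight

    def test_timezone_offset_shifts_midnight(self):
        midnight_utc = 86400.0 * 20000
        _, _, frm = features.window_time_metrics(midnight_utc, 1,
                                                 tz_offset=3600.0)
        assert frm[0] == pytest.approx(3600.0)


class TestEdaWindowMetrics:
    def test_constant_baseline(self):
        n = 70 * 80
        decomp = EdaDecomposition(stream(np.full(n, 2.5)), stream(np.zeros(n)))
        m = features.eda_window_metrics(decomp, 70)
        np.testing.assert_allclose(m["avg_eda_level"], 2.5)
        np.testing.assert_allclose(m["eda_slope_20s"], 0.0, atol=1e-12)
        np.testing.assert_allclose(m["eda_slope_120s"], 0.0, atol=1e-12)
        # zero-variance history population: z scores stay missing
        assert np.isnan(m["avg_eda_level_z"]).all()
        assert np.isnan(m["rms_eda_z"]).all()
        # difference against a constant history is defined, and zero
        assert m["avg_eda_level_diff"][65] == pytest.approx(0.0)

    def test_linear_baseline_slope(self):
        n = 8 * 80
        t = np.arange(n) / 4.0
        decomp = EdaDecomposition(stream(0.5 + 0.01 * t), stream(np.zeros(n)))
        m = features.eda_window_metrics(decomp, 8)
        np.testing.assert_allclose(m["eda_slope_20s"], 0.01, atol=1e-12)
        np.testing.assert_allclose(m["eda_slope_120s"][3:5], 0.01, atol=1e-12)

    def test_rms_of_sine_closed_form(self):
        t = np.arange(0, 1200, 0.25)
        bp = 0.2 * np.sin(2 * np.pi * 0.2 * t)
        decomp = EdaDecomposition(stream(np.zeros(len(t))), stream(bp))
        m = features.eda_window_metrics(decomp, 60)
        np.testing.assert_allclose(m["rms_eda"], 0.2 / math.sqrt(2), rtol=1e-9)

    def test_history_window_count(self):
        """Normalized metrics need the 60 windows from 20:20 to 0:20 before
        the time stamp, so exactly the first 61 windows are missing."""
        rng = np.random.default_rng(7)
        n_win = 70
        base = 1.0 + 0.05 * rng.standard_normal(n_win * 80)
        decomp = EdaDecomposition(stream(base), stream(base * 0.01))
        m = features.eda_window_metrics(decomp, n_win)
        for key in ("avg_eda_level_diff", "avg_eda_level_z",
                    "rms_eda_diff", "rms_eda_z"):
            assert np.isnan(m[key][:61]).all()
            assert np.isfinite(m[key][61:]).all()

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        x = 1.0 + 0.05 * rng.standard_normal(70 * 80)
        c = 3.7
        ma = features.eda_window_metrics(
            features.decompose_eda(stream(x)), 70)
        mb = features.eda_window_metrics(
            features.decompose_eda(stream(x + c)), 70)
        np.testing.assert_allclose(mb["avg_eda_level"],
                                   ma["avg_eda_level"] + c, atol=1e-9)
        for key in ("avg_eda_level_diff", "avg_eda_level_z", "eda_slope_20s",
                    "eda_slope_120s", "rms_eda", "rms_eda_diff", "rms_eda_z"):
            np.testing.assert_allclose(mb[key], ma[key], atol=1e-9)


def bruteforce_peaks(x, threshold, min_sep_samples):
    """Independent oracle: enumerate local maxima, prune greedily by height
    (ties: earlier index wins)."""
    maxima = [
        i for i in range(1, len(x) - 1)
        if x[i] >= x[i - 1] and x[i] > x[i + 1] and x[i] >= threshold
    ]
    kept = []
    for i in sorted(maxima, key=lambda i: (-x[i], i)):
        if all(abs(i - j) >= min_sep_samples for j in kept):
            kept.append(i)
    return sorted(kept)


class TestDetectPeaks:
    def test_all_below_threshold_empty(self):
        t, h = features.detect_peaks(np.sin(np.arange(80)) * 0.01, 0.15)
        assert len(t) == 0

    def test_separation_rule_keeps_larger(self):
        x = np.zeros(40)
        x[10] = 1.0
        x[12] = 0.9  # 0.5 s away at 4 Hz
        t, h = features.detect_peaks(x, 0.15, min_separation=1.0)
        assert list(h) == [1.0]
        assert t[0] == pytest.approx(10 / 4.0)

    def test_exactly_at_separation_both_kept(self):
        x = np.zeros(40)
        x[10] = 1.0
        x[14] = 0.9  # exactly 1 s
        t, h = features.detect_peaks(x, 0.15, min_separation=1.0)
        assert len(t) == 2

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 0.1, 80)
        t, h = features.detect_peaks(x, 0.05, min_separation=1.0)
        want = bruteforce_peaks(x, 0.05, 4)
        np.testing.assert_array_equal((t * 4).astype(int), want)
        np.testing.assert_allclose(h, x[want])


class TestPeakMetrics:
    def build_decomp(self, amplitude):
        n = 80
        bp = np.zeros(n)
        bp[30:37] = amplitude * np.array([0.2, 0.6, 0.9, 1.0, 0.8, 0.5, 0.2])
        return EdaDecomposition(stream(np.zeros(n)), stream(bp))

    def test_large_scr_counted_at_both_thresholds(self):
        m = features.peak_metrics(self.build_decomp(0.5), 1)
        assert m["n_peaks_high"][0] == 1 and m["n_peaks_low"][0] == 1
        assert m["avg_peak_height_high"][0] == pytest.approx(0.5)

    def test_small_scr_counted_at_low_threshold_only(self):
        m = features.peak_metrics(self.build_decomp(0.05), 1)
        assert m["n_peaks_high"][0] == 0 and m["n_peaks_low"][0] == 1
        assert np.isnan(m["avg_peak_height_high"][0])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_low_count_dominates_high_count(self, seed):
        rng = np.random.default_rng(seed)
        bp = rng.normal(0, 0.1, 6 * 80)
        decomp = EdaDecomposition(stream(np.zeros(len(bp))), stream(bp))
        m = features.peak_metrics(decomp, 6)
        assert np.all(m["n_peaks_low"] >= m["n_peaks_high"])

    def test_peak_heights_at_least_threshold(self, rng):
        bp = rng.normal(0, 0.15, 10 * 80)
        decomp = EdaDecomposition(stream(np.zeros(len(bp))), stream(bp))
        m = features.peak_metrics(decomp, 10)
        ok = m["n_peaks_high"] > 0
        assert np.all(m["avg_peak_height_high"][ok] >= 0.15)


class TestQualityFlags:
    def test_clean_session_all_good(self, short_shift):
        flags = features.quality_flags(short_shift.session)
        assert np.all(flags == 1)
        assert len(flags) == math.ceil(short_shift.session.eda.duration / 5)

    def test_zeroed_eda_flags_two_intervals(self, short_shift):
        session = short_shift.session
        eda = session.eda.values.copy()
        eda[400:440] = 0.0  # 10 s at 4 Hz
        import dataclasses
        patched = dataclasses.replace(
            session, eda=RawStream(session.start_time, 4.0, eda))
        flags = features.quality_flags(patched)
        assert (flags == -1).sum() == 2
        assert flags[20] == -1 and flags[21] == -1

    def test_temperature_excursion_flags_interval(self, short_shift):
        session = short_shift.session
        temp = session.temp.values.copy()
        temp[100:120] = 50.0
        import dataclasses
        patched = dataclasses.replace(
            session, temp=RawStream(session.start_time, 4.0, temp))
        flags = features.quality_flags(patched)
        assert flags[5] == -1


class TestBadDataValues:
    @pytest.mark.parametrize(
        "flags, want",
        [
            ([1, 1, 1, 1], 4),     # all good (100%)
            ([1, 1, 1, -1], 2),    # one bad (75%)
            ([1, 1, -1, -1], 0),   # two bad (50%)
            ([1, -1, -1, -1], -2),  # three bad (25%)
            ([-1, -1, -1, -1], -4),  # all bad (0%)
        ],
    )
    def test_printed_mapping(self, flags, want):
        out = features.bad_data_values(np.array(flags), 1)
        assert out[0] == want

    def test_short_flag_stream_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            features.bad_data_values(np.ones(7, dtype=int), 2)


class TestExtractMetrics:
    def test_shape_and_columns(self, short_shift):
        table = features.extract_metrics(short_shift.session)
        assert len(table) == 180  # 1 h / 20 s
        assert list(table.columns) == METRIC_COLUMNS
        assert len(table.columns) == 19
        assert len([c for c in table.columns if c in EDA_COLUMNS]) == 12

    def test_naive_loop_oracle(self, quiet_config):
        """Every windowed metric equals an independent naive per-window loop
        on a random 10-minute session."""
        cfg = quiet_config
        session = synthgen.synth_session(cfg)
        config = FeatureConfig()
        ev = np.zeros(int(session.duration))
        table = features.extract_metrics(session, ev, config)
        n = len(table)

        decomp = features.decompose_eda(session.eda, config)
        act = features.activity_signal(session.acc, config)
        flags = features.quality_flags(session, config)
        baseline, bandpass = decomp.baseline.values, decomp.bandpass.values

        hist, lag = config.history_windows, config.history_lag
        level = [baseline[80 * k: 80 * (k + 1)].mean() for k in range(n)]
        rms = [
            np.sqrt((bandpass[80 * k: 80 * (k + 1)] ** 2).mean())
            for k in range(n)
        ]
        for k in range(n):
            row = table.iloc[k]
            assert row["time_stamp"] == cfg.shift_start + 20 * k
            assert row["elapsed_time"] == 20.0 * k
            assert row["elapsed_from_midnight"] == pytest.approx(
                (cfg.shift_start + 20 * k) % 86400.0)
            assert row["event_code"] == 0.0
            assert row["bad_data_value"] == flags[4 * k: 4 * (k + 1)].sum()
            counts = [
                np.abs(act.values[32 * s: 32 * (s + 1)]).sum()
                for s in range(20 * k, 20 * (k + 1))
            ]
            assert row["avg_activity_count"] == pytest.approx(
                np.mean(counts), abs=1e-9)
            assert row["avg_temp"] == pytest.approx(
                session.temp.values[80 * k: 80 * (k + 1)].mean(), abs=1e-9)
            assert row["avg_eda_level"] == pytest.approx(level[k], abs=1e-9)
            assert row["rms_eda"] == pytest.approx(rms[k], abs=1e-9)
            t_abs = np.arange(80 * k, 80 * (k + 1)) / 4.0
            slope = np.polyfit(t_abs, baseline[80 * k: 80 * (k + 1)], 1)[0]
            assert row["eda_slope_20s"] == pytest.approx(slope, abs=1e-9)
            mid = 80 * k + 40
            i0, i1 = max(0, mid - 240), min(len(baseline), mid + 240)
            if i1 - i0 >= 240:
                slope120 = np.polyfit(np.arange(i0, i1) / 4.0,
                                      baseline[i0:i1], 1)[0]
                assert row["eda_slope_120s"] == pytest.approx(slope120,
                                                              abs=1e-9)
            else:
                assert np.isnan(row["eda_slope_120s"])
            for name, series in (("avg_eda_level", level), ("rms_eda", rms)):
                key = "avg_eda_level" if name == "avg_eda_level" else "rms_eda"
                pop = series[k - hist - lag: k - lag] if k >= hist + lag else []
                if len(pop) == hist:
                    mu, sd = np.mean(pop), np.std(pop, ddof=1)
                    assert row[f"{key}_diff"] == pytest.approx(
                        series[k] - mu, abs=1e-9)
                    assert row[f"{key}_z"] == pytest.approx(
                        (series[k] - mu) / sd, abs=1e-9)
                else:
                    assert np.isnan(row[f"{key}_diff"])
                    assert np.isnan(row[f"{key}_z"])
            for nm, thr in (("high", config.peak_high), ("low", config.peak_low)):
                want = bruteforce_peaks(bandpass[80 * k: 80 * (k + 1)], thr, 4)
                assert row[f"n_peaks_{nm}"] == len(want)
                if want:
                    assert row[f"avg_peak_height_{nm}"] == pytest.approx(
                        np.mean(bandpass[80 * k: 80 * (k + 1)][want]),
                        abs=1e-9)
                else:
                    assert np.isnan(row[f"avg_peak_height_{nm}"])
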