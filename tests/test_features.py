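"""Event detection and the five-family inventory, with independent oracles."""

import dataclasses
import warnings

import numpy as np
import pytest

import fingertap as ft
from fingertap.features import MEASURE_NAMES, PROFILES

from conftest import make_signal


def entropy_oracle(x: np.ndarray, bins: int = 16) -> float:
    """Brute-force histogram Shannon entropy (nats), equal-width bins."""
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    counts = [0] * bins
    for v in x:
        b = int((v - lo) / (hi - lo) * bins)
        counts[min(b, bins - 1)] += 1
    h = 0.0
    for c in counts:
        if c:
            p = c / len(x)
            h -= p * np.log(p)
    return h


class TestSummaryMeasures:
    def test_hand_arithmetic(self):
        m = ft.summary_measures([1, 2, 3, 4])
        assert m["mean"] == 2.5 and m["max"] == 4 and m["min"] == 1
        assert m["median"] == 2.5 and m["range"] == 3 and m["iqr"] == 1.5

    def test_constant_sequence_degenerate(self):
        m = ft.summary_measures(np.full(20, 7.0))
        assert m["std"] == 0 and m["range"] == 0 and m["iqr"] == 0 and m["entropy"] == 0

    def test_canonical_order_and_count(self):
        m = ft.summary_measures(np.arange(10.0))
        assert tuple(m.keys()) == MEASURE_NAMES
        assert len(m) == 11

    @pytest.mark.parametrize("seed", [0, 3])
    def test_entropy_matches_independent_oracle(self, seed):
        x = np.random.default_rng(seed).uniform(size=10_000)
        m = ft.summary_measures(x)
        assert abs(m["entropy"] - entropy_oracle(x)) < 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(ft.InsufficientDataError):
            ft.summary_measures([1.0])


class TestEventDetection:
    def test_clean_signal_event_counts(self, clean_signal):
        ev = ft.detect_events(clean_signal)
        assert ev.n_peaks == 30
        assert ev.n_troughs == 29
        t, _ = ev.interleaved()
        assert np.all(np.diff(t) > 0)

    def test_alternation_and_amplitude_ordering(self, noisy_ataxia_signal):
        ev = ft.detect_events(noisy_ataxia_signal)
        for i in range(ev.n_troughs):
            assert ev.peak_times[i] < ev.trough_times[i] < ev.peak_times[i + 1]
            assert ev.peak_amps[i] > ev.trough_amps[i]
            assert ev.peak_amps[i + 1] > ev.trough_amps[i]

    def test_constant_signal_too_few_events(self):
        sig = make_signal(np.zeros(300))
        with pytest.raises(ft.TooFewEventsError):
            ft.detect_events(sig)

    def test_cosine_trough_periods(self):
        t = np.arange(450) / 30
        sig = make_signal(ft.zscore(np.cos(2 * np.pi * 2 * t)))
        ev = ft.detect_events(sig)
        intervals = np.diff(ev.trough_times)
        assert np.all(np.abs(intervals - 0.5) <= 1 / 30 + 1e-9)

    def test_alternation_invariant_over_random_cohorts(self):
        # random phenotypes within documented ranges never break alternation
        rng = np.random.default_rng(99)
        for _ in range(60):
            params = ft.PhenotypeParams(
                tap_rate_hz=rng.uniform(1.0, 4.0),
                period_cv=rng.uniform(0, 0.3),
                amp_cv=rng.uniform(0, 0.3),
                amp_slope=rng.uniform(-0.03, 0.0),
                jitter_sd_px=rng.uniform(0, 2.0),
            )
            rec, _ = ft.generate_tapping_recording(params, seed=int(rng.integers(2**31)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sig = ft.preprocess_recording(rec)
            try:
                ev = ft.detect_events(sig)
            except ft.FingertapError:
                continue
            t, _ = ev.interleaved()
            assert np.all(np.diff(t) > 0)
            assert ev.n_troughs == ev.n_peaks - 1


class TestTSFamily:
    def test_zscored_identity_features(self, clean_signal):
        feats = ft.ts_family(clean_signal)
        assert abs(feats["amp_mean"]) < 1e-9
        assert abs(feats["amp_std"] - 1) < 1e-9
        assert len(feats) == 45

    def test_spectral_peak_of_clean_2hz(self, clean_signal):
        assert abs(ft.spectral_peak_frequency(clean_signal) - 2.0) <= 0.25

    def test_spectral_flag_off(self, clean_signal):
        assert len(ft.ts_family(clean_signal, include_spectral=False)) == 44


class TestEventFamilies:
    def _events(self, amps, times):
        amps = np.asarray(amps, float)
        times = np.asarray(times, float)
        troughs = 0.5 * (times[:-1] + times[1:])
        return ft.TapEvents(
            peak_times=times, peak_amps=amps,
            trough_times=troughs, trough_amps=amps[:-1] * 0 - 1,
        )

    def test_constant_amplitudes_zero_measures(self):
        ev = self._events(np.ones(12), np.arange(12) * 0.5)
        feats = ft.event_family(ev, "peaks")
        assert abs(feats["slope"]) < 1e-12
        for k in (1, 2, 3):
            assert abs(feats[f"d{k}_mean"]) < 1e-12 and abs(feats[f"d{k}_std"]) < 1e-12

    def test_linear_decay_slope_recovered(self):
        times = np.arange(20) * 0.47
        amps = 1 - 0.05 * times
        feats = ft.event_family(self._events(amps, times), "peaks")
        assert abs(feats["slope"] + 0.05) < 1e-6

    def test_feature_count_by_depth(self):
        ev = self._events(np.sin(np.arange(20)), np.arange(20) * 0.4)
        assert len(ft.event_family(ev, "peaks", derivative_depth=3)) == 45
        assert len(ft.event_family(ev, "peaks", derivative_depth=2)) == 34

    def test_amp_cv_increases_peak_spread(self):
        # Monte-Carlo: higher amplitude CV -> larger std of detected peaks
        wins = 0
        for seed in range(25):
            stds = {}
            for cv in (0.05, 0.3):
                params = ft.PhenotypeParams(tap_rate_hz=2.0, amp_cv=cv, period_cv=0.05)
                rec, _ = ft.generate_tapping_recording(params, seed=seed)
                sig = ft.preprocess_recording(rec, ft.PreprocessConfig(lowpass=False))
                ev = ft.detect_events(sig)
                stds[cv] = ev.peak_amps.std()
            wins += stds[0.3] > stds[0.05]
        assert wins >= 23


class TestPkTh:
    def test_symmetric_clean_half_cycle(self, clean_signal):
        ev = ft.detect_events(clean_signal)
        feats = ft.pkth_family(ev)
        assert abs(feats["dt_mean"] - 0.25) <= 1 / 30 + 1e-9
        assert feats["dt_std"] < 1e-9
        assert feats["damp_std"] < 1e-9
        assert feats["damp_mean"] > 0

    def test_matches_pairing_oracle(self):
        rng = np.random.default_rng(5)
        n = 15
        peak_t = np.cumsum(rng.uniform(0.3, 0.7, n))
        trough_t = peak_t[:-1] + rng.uniform(0.05, 0.2, n - 1)
        peak_a = rng.uniform(0.5, 1.5, n)
        trough_a = rng.uniform(-1.5, -0.5, n - 1)
        ev = ft.TapEvents(peak_t, peak_a, trough_t, trough_a)
        feats = ft.pkth_family(ev)
        # brute-force pairing, written independently
        dts, damps = [], []
        for i, tt in enumerate(trough_t):
            preceding = [j for j, pt in enumerate(peak_t) if pt < tt]
            j = preceding[-1]
            dts.append(tt - peak_t[j])
            damps.append(peak_a[j] - trough_a[i])
        assert feats["dt_mean"] == pytest.approx(np.mean(dts), abs=1e-12)
        assert feats["dt_median"] == pytest.approx(np.median(dts), abs=1e-12)
        assert feats["damp_std"] == pytest.approx(np.std(damps), abs=1e-12)


class TestThTh:
    def test_exact_parabola_recovery(self):
        tau = np.linspace(0, 1, 16)
        y = 4 * tau * (1 - tau)
        sig = make_signal(np.concatenate([y, y[1:], y[1:]]))
        ev = ft.TapEvents(
            peak_times=np.array([7.5, 22.5, 37.5]) / 30,
            peak_amps=np.array([1.0, 1.0, 1.0]),
            trough_times=np.array([0, 15, 30, 45]) / 30,
            trough_amps=np.zeros(4),
        )
        fits = ft.fit_cycles(sig, ev)
        for f in fits:
            assert abs(f.a + 4) < 1e-9 and abs(f.b - 4) < 1e-9 and abs(f.c) < 1e-9
            assert f.rss < 1e-9

    def test_clean_signal_cycles_exact(self, clean_signal):
        ev = ft.detect_events(clean_signal)
        fits, feats = ft.thth_family(clean_signal, ev)
        assert max(f.rss for f in fits) < 1e-9
        assert feats["a_std"] < 1e-9
        assert all(f.a < 0 for f in fits)

    def test_matches_normal_equations_oracle(self, noisy_ataxia_signal):
        ev = ft.detect_events(noisy_ataxia_signal)
        fits, _ = ft.thth_family(noisy_ataxia_signal, ev)
        fs = noisy_ataxia_signal.fs
        for f in fits:
            i0, i1 = int(round(f.t_start * fs)), int(round(f.t_end * fs))
            y = noisy_ataxia_signal.amplitude[i0:i1 + 1]
            tau = np.linspace(0, 1, len(y))
            X = np.column_stack([tau**2, tau, np.ones_like(tau)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert abs(beta[0] - f.a) < 1e-8
            assert abs(beta[1] - f.b) < 1e-8
            assert abs(beta[2] - f.c) < 1e-8


class TestProfilesAndExtraction:
    def test_paper_total_is_256_over_two_hands(self, clean_signal):
        vec, manifest = ft.extract_features(clean_signal, clean_signal, "paper-total")
        assert manifest["total"] == 256
        assert len(vec) == 256
        assert sum(manifest["per_family_counts"].values()) == 256

    def test_canonical_counts(self, clean_signal):
        vec, manifest = ft.extract_features(clean_signal, clean_signal, "canonical")
        per_hand = manifest["per_hand_expected"]
        assert per_hand == {"TS": 45, "Pk": 45, "Th": 45, "PkTh": 6, "ThTh": 3}
        # 143 core features per hand + the flagged spectral extension
        assert sum(per_hand.values()) == 144
        assert manifest["total"] == 288

    def test_names_unique_ordered_deterministic(self, clean_signal):
        v1, _ = ft.extract_features(clean_signal, clean_signal, "canonical")
        v2, _ = ft.extract_features(clean_signal, clean_signal, "canonical")
        assert list(v1) == list(v2)
        assert len(set(v1)) == len(v1)
        assert np.array_equal(list(v1.values()), list(v2.values()))

    def test_single_hand_mode(self, clean_signal):
        vec, manifest = ft.extract_features(clean_signal, None, "paper-total")
        assert manifest["total"] == 128
        assert all(".dominant." in k for k in vec)

    def test_all_features_finite_on_noisy_cohort(self, cohort_features):
        table, _, _ = cohort_features
        assert np.isfinite(table.to_numpy()).all()

    def test_failure_names_hand(self):
        flat = make_signal(np.zeros(300))
        with pytest.raises(ft.FeatureExtractionError, match="dominant"):
            ft.extract_features(flat, None, "canonical")

    def test_profile_registry(self):
        assert set(PROFILES) == {"canonical", "paper-total"}
        p = PROFILES["paper-total"]
        assert sum(p.per_hand_counts().values()) == 128


class TestDirectionalSeparation:
    def test_ataxia_preset_directions(self):
        """Ataxia presets: longer periods, more variable curvature, lower
        spectral peak than control presets (small paired cohorts)."""
        res = {}
        for group, preset in (("ataxia", "ataxia"), ("control", "control")):
            periods, astds, freqs = [], [], []
            for seed in range(12):
                params = dataclasses.replace(ft.GROUP_PRESETS[preset], jitter_sd_px=1.5)
                rec, _ = ft.generate_tapping_recording(params, seed=seed)
                sig = ft.preprocess_recording(rec)
                ev = ft.detect_events(sig)
                _, th = ft.thth_family(sig, ev)
                periods.append(np.mean(np.diff(ev.trough_times)))
                astds.append(th["a_std"])
                freqs.append(ft.spectral_peak_frequency(sig))
            res[group] = (np.mean(periods), np.mean(astds), np.mean(freqs))
        assert res["ataxia"][0] > res["control"][0]
        assert res["ataxia"][1] > res["control"][1]
        assert res["ataxia"][2] < res["control"][2]
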