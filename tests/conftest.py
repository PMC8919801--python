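import dataclasses
import warnings

import numpy as np
import pytest

import fingertap as ft


def make_signal(x: np.ndarray, fs: int = 30) -> ft.TappingSignal:
    """Wrap a raw series as a TappingSignal with consistent derivatives."""
    v = np.gradient(x) * fs
    a = np.gradient(v) * fs
    j = np.gradient(a) * fs
    return ft.TappingSignal(fs=fs, amplitude=np.asarray(x, float), velocity=v,
                            acceleration=a, jerk=j)


@pytest.fixture(scope="session")
def clean_params() -> ft.PhenotypeParams:
    """Deterministic 2 Hz, 15 s, 30 Hz recording with no noise of any kind."""
    return ft.PhenotypeParams(
        tap_rate_hz=2.0, period_cv=0.0, amp_cv=0.0, amp_slope=0.0,
        jitter_sd_px=0.0, dropout_prob=0.0, outlier_prob=0.0,
        duration_s=15.0, fs=30,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_params):
    return ft.generate_tapping_recording(clean_params, seed=1)


@pytest.fixture(scope="session")
def clean_signal(clean_recording) -> ft.TappingSignal:
    """Preprocessed clean recording; filtering off so the parabolic cycle
    shape is preserved exactly."""
    rec, _ = clean_recording
    return ft.preprocess_recording(rec, ft.PreprocessConfig(lowpass=False))


@pytest.fixture(scope="session")
def noisy_ataxia_signal() -> ft.TappingSignal:
    params = dataclasses.replace(
        ft.GROUP_PRESETS["ataxia"], jitter_sd_px=1.5, dropout_prob=0.004,
        outlier_prob=0.003,
    )
    rec, _ = ft.generate_tapping_recording(params, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ft.preprocess_recording(rec)


@pytest.fixture(scope="session")
def cohort_60():
    """30 ataxia + 30 control sessions; reused by the model tests."""
    spec = ft.small_cohort_spec(30, 0, 30, seed=11)
    return ft.generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_features(cohort_60):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        signals, _, _ = ft.preprocess_cohort(cohort_60)
        table, manifest = ft.features_table(signals, "paper-total")
    meta = ft.add_common_scores(cohort_60.manifest).set_index("session_id").loc[table.index]
    return table, meta, manifest
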