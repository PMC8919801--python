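"""Synthetic finger-tapping cohorts with controllable phenotype structure.

Real assessments film a seated participant tapping index finger against
thumb for ~15 s per hand while a pose tracker emits per-frame landmark
coordinates.  This module emulates that output directly: each recording is
a train of tap cycles whose period and peak amplitude vary according to a
phenotype parameterization, rendered as index/thumb/wrist landmark tracks
and corrupted with tracker jitter, dropouts and spike outliers.

The three group presets encode the clinically reported directions of
impairment: ataxia taps slower with markedly irregular period and
amplitude; parkinsonism shows a progressive amplitude decrement; controls
tap fast and regularly.  Magnitudes are package defaults (no public
quantitative reference exists) and every axis is configurable.

Within a cycle of period ``T_k`` the index–thumb distance follows the
downward parabola ``d(tau) = A_k * 4*tau*(1-tau)`` on normalized cycle time
``tau`` — zero at the troughs (finger on thumb), maximal mid-cycle — so the
trough-to-trough quadratic parameterization used downstream is exact on
clean data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, ParameterError
from .recording import LANDMARKS, LandmarkRecording

#: Healthy reference tap rate (Hz) used by the severity map's rate-deficit term.
HEALTHY_RATE_HZ = 3.0

# Fixed scene geometry (pixels, 960x540 frame): thumb anchored, index moves
# away along a fixed unit direction, wrist static.
_THUMB_POS = np.array([480.0, 300.0])
_TAP_DIRECTION = np.array([np.cos(-1.05), np.sin(-1.05)])  # up-right on screen
_WRIST_OFFSET = np.array([-40.0, 80.0])


@dataclass(frozen=True)
class PhenotypeParams:
    """Generative parameters for one recording.

    Parameters
    ----------
    tap_rate_hz : float
        Mean tap frequency (Hz); must be positive.
    period_cv : float
        Coefficient of variation of the cycle period (rhythm irregularity).
    amp_cv : float
        Coefficient of variation of the peak amplitude.
    amp_slope : float
        Fractional amplitude change per second; negative values give the
        parkinsonian amplitude decrement.
    base_amp_px : float
        Mean peak index–thumb separation in pixels.
    jitter_sd_px : float
        Per-frame isotropic Gaussian landmark noise (pixels).
    dropout_prob : float
        Per-frame probability of starting a missing-sample gap.
    dropout_mean_len_s : float
        Mean gap length in seconds (geometric length distribution).
    outlier_prob : float
        Per-frame probability of a spike outlier on the index fingertip.
    outlier_mag_px : float
        Spike magnitude in pixels.
    duration_s : float
        Recording length in seconds.
    fs : int
        Sampling rate; 30 or 60 Hz.
    """

    tap_rate_hz: float = 3.0
    period_cv: float = 0.05
    amp_cv: float = 0.08
    amp_slope: float = 0.0
    base_amp_px: float = 100.0
    jitter_sd_px: float = 0.0
    dropout_prob: float = 0.0
    dropout_mean_len_s: float = 0.2
    outlier_prob: float = 0.0
    outlier_mag_px: float = 60.0
    duration_s: float = 15.0
    fs: int = 30

    def validate(self) -> None:
        if not self.tap_rate_hz > 0:
            raise ParameterError(f"tap_rate_hz must be > 0, got {self.tap_rate_hz}")
        for name in ("period_cv", "amp_cv"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("dropout_prob", "outlier_prob"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ParameterError(f"{name} must be in [0, 1), got {v}")
        if self.fs not in (30, 60):
            raise ParameterError(f"fs must be 30 or 60, got {self.fs}")
        if not self.duration_s > 0:
            raise ParameterError(f"duration_s must be > 0, got {self.duration_s}")
        if not self.base_amp_px > 0:
            raise ParameterError(f"base_amp_px must be > 0, got {self.base_amp_px}")


#: Group presets encoding the reported directions of impairment.
GROUP_PRESETS: dict[str, PhenotypeParams] = {
    "control": PhenotypeParams(tap_rate_hz=3.0, period_cv=0.05, amp_cv=0.08, amp_slope=0.0),
    "ataxia": PhenotypeParams(tap_rate_hz=1.8, period_cv=0.25, amp_cv=0.25, amp_slope=0.0),
    "parkinsonism": PhenotypeParams(tap_rate_hz=2.8, period_cv=0.10, amp_cv=0.12, amp_slope=-0.03),
}

#: Realistic tracker-noise defaults shared by all groups in cohort generation.
NOISE_DEFAULTS = dict(
    jitter_sd_px=1.5,
    dropout_prob=0.004,
    dropout_mean_len_s=0.2,
    outlier_prob=0.003,
    outlier_mag_px=60.0,
)


@dataclass
class GroundTruth:
    """Noise-free generative record for one recording.

    ``amplitude_trace`` is the clean index–thumb distance at every frame
    (pixels); ``cycle_periods`` and ``peak_amps`` cover the complete cycles
    that fit inside the recording; ``severity`` is the scalar in [0, 1]
    produced by :func:`severity_from_params`.
    """

    amplitude_trace: np.ndarray
    cycle_starts: np.ndarray
    cycle_periods: np.ndarray
    peak_amps: np.ndarray
    severity: float = 0.0

    def to_dict(self) -> dict:
        return {
            "amplitude_trace": self.amplitude_trace.tolist(),
            "cycle_starts": self.cycle_starts.tolist(),
            "cycle_periods": self.cycle_periods.tolist(),
            "peak_amps": self.peak_amps.tolist(),
            "severity": self.severity,
        }


@dataclass(frozen=True)
class SeverityCoeffs:
    """Weights of the monotone severity map.

    severity = w_period * period_cv + w_amp * amp_cv
             + w_rate * max(0, 1 - tap_rate / reference_rate), clipped to [0, 1].
    """

    w_period: float = 1.0
    w_amp: float = 0.6
    w_rate: float = 0.8
    reference_rate_hz: float = HEALTHY_RATE_HZ


def severity_from_params(
    params: PhenotypeParams,
    group: str,
    coeffs: SeverityCoeffs = SeverityCoeffs(),
) -> float:
    """Deterministic monotone severity in [0, 1]; controls are exactly 0.

    Severity grows with rhythm irregularity (period_cv), force/amplitude
    irregularity (amp_cv), and slowing below the healthy reference rate,
    mirroring how clinical scales grade the impairment axes.
    """
    params.validate()
    if group == "control":
        return 0.0
    rate_deficit = max(0.0, 1.0 - params.tap_rate_hz / coeffs.reference_rate_hz)
    s = (
        coeffs.w_period * params.period_cv
        + coeffs.w_amp * params.amp_cv
        + coeffs.w_rate * rate_deficit
    )
    return float(np.clip(s, 0.0, 1.0))


def _draw_cycles(params: PhenotypeParams, rng: np.random.Generator):
    """Sample cycle periods/amplitudes covering the recording duration.

    Truncated-normal multipliers (floors 0.2 for period, 0.1 for amplitude)
    keep periods and amplitudes positive at high CV.
    """
    starts, periods, amps = [], [], []
    t = 0.0
    mean_period = 1.0 / params.tap_rate_hz
    while t < params.duration_s:
        eps = rng.standard_normal()
        T = mean_period * max(0.2, 1.0 + params.period_cv * eps)
        eta = rng.standard_normal()
        A = (
            params.base_amp_px
            * (1.0 + params.amp_slope * t)
            * max(0.1, 1.0 + params.amp_cv * eta)
        )
        A = max(A, 0.02 * params.base_amp_px)
        starts.append(t)
        periods.append(T)
        amps.append(A)
        t += T
    return np.array(starts), np.array(periods), np.array(amps)


def generate_tapping_recording(
    params: PhenotypeParams,
    seed: int,
    hand: str = "dominant",
    subject_id: str = "s0",
    session_id: str = "s0_v0",
    group: str = "control",
    severity_coeffs: SeverityCoeffs = SeverityCoeffs(),
) -> tuple[LandmarkRecording, GroundTruth]:
    """Simulate one landmark recording and its generative ground truth.

    Deterministic given ``(params, seed)``.  The clean distance trace is a
    concatenation of per-cycle parabolas; landmarks are then corrupted with
    i.i.d. Gaussian jitter, geometric-length dropout gaps (all landmarks
    missing, confidence 0) and isolated spike outliers on the index tip.
    """
    params.validate()
    rng = np.random.default_rng(seed)

    starts, periods, amps = _draw_cycles(params, rng)
    n = int(round(params.duration_s * params.fs))
    t_frames = np.arange(n) / params.fs

    # Locate each frame's cycle and evaluate the parabola.
    idx = np.searchsorted(starts, t_frames, side="right") - 1
    tau = (t_frames - starts[idx]) / periods[idx]
    clean = amps[idx] * 4.0 * tau * (1.0 - tau)

    complete = (starts + periods) <= params.duration_s + 1e-9
    truth = GroundTruth(
        amplitude_trace=clean,
        cycle_starts=starts[complete],
        cycle_periods=periods[complete],
        peak_amps=amps[complete],
        severity=severity_from_params(params, group, severity_coeffs),
    )

    xy = {
        "thumb_tip": np.tile(_THUMB_POS, (n, 1)),
        "index_tip": _THUMB_POS + clean[:, None] * _TAP_DIRECTION,
        "wrist": np.tile(_THUMB_POS + _WRIST_OFFSET, (n, 1)),
    }
    conf = {name: np.ones(n) for name in LANDMARKS}

    if params.jitter_sd_px > 0:
        for name in LANDMARKS:
            xy[name] = xy[name] + rng.normal(0.0, params.jitter_sd_px, size=(n, 2))

    # Spike outliers: a single-frame displacement of the index tip.
    if params.outlier_prob > 0:
        spikes = rng.random(n) < params.outlier_prob
        angles = rng.uniform(0, 2 * np.pi, size=n)
        disp = params.outlier_mag_px * np.column_stack([np.cos(angles), np.sin(angles)])
        xy["index_tip"] = xy["index_tip"] + spikes[:, None] * disp

    # Dropout gaps: tracker loses the hand for a geometric-length run.
    if params.dropout_prob > 0:
        gap_starts = rng.random(n) < params.dropout_prob
        p_stop = 1.0 / max(params.dropout_mean_len_s * params.fs, 1.0)
        lengths = rng.geometric(p_stop, size=n)
        missing = np.zeros(n, dtype=bool)
        for i in np.nonzero(gap_starts)[0]:
            missing[i : i + lengths[i]] = True
        for name in LANDMARKS:
            xy[name] = xy[name].copy()
            xy[name][missing] = np.nan
            conf[name] = np.where(missing, 0.0, conf[name])

    rec = LandmarkRecording(
        fs=params.fs,
        frames=np.arange(n),
        xy=xy,
        confidence=conf,
        hand=hand,
        subject_id=subject_id,
        session_id=session_id,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Per-group cohort settings: counts, ages, phenotype spread."""

    n_videos: int
    n_repeat_videos: int
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    preset: PhenotypeParams
    # SDs of per-subject draws around the preset means.
    rate_sd: float = 0.25
    period_cv_sd: float = 0.02
    amp_cv_sd: float = 0.02
    slope_sd: float = 0.0

    @property
    def repeat_fraction(self) -> float:
        return self.n_repeat_videos / self.n_videos if self.n_videos else 0.0


def _default_groups() -> dict[str, GroupSpec]:
    noisy = lambda g: replace(GROUP_PRESETS[g], **NOISE_DEFAULTS)  # noqa: E731
    return {
        "ataxia": GroupSpec(
            n_videos=169, n_repeat_videos=41,
            age_mean=49, age_sd=22.4, age_range=(5, 82),
            preset=noisy("ataxia"),
            rate_sd=0.40, period_cv_sd=0.10, amp_cv_sd=0.08, slope_sd=0.01,
        ),
        "parkinsonism": GroupSpec(
            n_videos=74, n_repeat_videos=13,
            age_mean=67, age_sd=7.7, age_range=(45, 85),
            preset=noisy("parkinsonism"),
            rate_sd=0.30, period_cv_sd=0.04, amp_cv_sd=0.05, slope_sd=0.015,
        ),
        "control": GroupSpec(
            n_videos=58, n_repeat_videos=8,
            age_mean=30, age_sd=20.2, age_range=(4, 86),
            preset=noisy("control"),
            rate_sd=0.25, period_cv_sd=0.015, amp_cv_sd=0.02, slope_sd=0.0,
        ),
    }


@dataclass
class CohortSpec:
    """Full cohort specification; defaults mirror the study demographics."""

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    severity_coeffs: SeverityCoeffs = SeverityCoeffs()
    hand_jitter_frac: float = 0.05  # small dominant/nondominant asymmetry
    seed: int = 0

    def validate(self) -> None:
        for name, g in self.groups.items():
            if g.n_videos < 0:
                raise ParameterError(f"group {name}: n_videos must be >= 0")
            if not (0 <= g.repeat_fraction < 1):
                raise ParameterError(f"group {name}: repeat fraction must be in [0, 1)")
        if sum(g.n_videos for g in self.groups.values()) == 0:
            raise EmptyDatasetError("cohort spec has zero recordings")


@dataclass
class CohortDataset:
    """Generated cohort: landmark recordings plus a session-level manifest.

    ``recordings`` and ``ground_truth`` are keyed by ``(session_id, hand)``;
    the manifest holds one row per session with group, age and clinical
    scores for both arms.
    """

    recordings: dict[tuple[str, str], LandmarkRecording]
    ground_truth: dict[tuple[str, str], GroundTruth]
    manifest: pd.DataFrame

    @property
    def n_sessions(self) -> int:
        return len(self.manifest)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        for (session_id, hand), rec in self.recordings.items():
            stem = f"{session_id}_{hand}"
            rec.write_csv(out / f"{stem}.csv")
            gt = self.ground_truth[(session_id, hand)]
            (out / f"{stem}.truth.json").write_text(json.dumps(gt.to_dict()))


def _round_half(x: float) -> float:
    return round(x * 2.0) / 2.0


def _subject_params(g: GroupSpec, rng: np.random.Generator) -> PhenotypeParams:
    """Draw one subject's phenotype around the group preset."""
    p = g.preset
    rate = float(np.clip(rng.normal(p.tap_rate_hz, g.rate_sd), 0.8, 4.5))
    pcv = float(max(rng.normal(p.period_cv, g.period_cv_sd), 0.01))
    acv = float(max(rng.normal(p.amp_cv, g.amp_cv_sd), 0.01))
    slope = float(rng.normal(p.amp_slope, g.slope_sd))
    if p.amp_slope < 0:
        slope = min(slope, 0.0)
    return dataclasses.replace(p, tap_rate_hz=rate, period_cv=pcv, amp_cv=acv, amp_slope=slope)


def _hand_variant(params: PhenotypeParams, frac: float, rng: np.random.Generator) -> PhenotypeParams:
    """Mild per-hand perturbation of the subject-level phenotype."""
    if frac <= 0:
        return params
    m = lambda: float(max(rng.normal(1.0, frac), 0.5))  # noqa: E731
    return dataclasses.replace(
        params,
        tap_rate_hz=params.tap_rate_hz * m(),
        period_cv=params.period_cv * m(),
        amp_cv=params.amp_cv * m(),
    )


def _clinical_scores(group: str, sev_d: float, sev_nd: float, rng: np.random.Generator) -> dict:
    """Map generative severities to plausible clinical scale values.

    Ataxia arms carry a 0–4 score in 0.5 steps; the parkinsonism arm
    composite spans 0–12 (three bradykinesia items); totals scale the arm
    burden up with mild noise.  Controls are all zero.
    """
    out = dict(
        bars_arm_dominant=0.0, bars_arm_nondominant=0.0, bars_total=0.0,
        updrs_arm_dominant=0.0, updrs_arm_nondominant=0.0, updrs_total=0.0,
    )
    if group == "ataxia":
        out["bars_arm_dominant"] = float(np.clip(_round_half(sev_d * 4), 0, 4))
        out["bars_arm_nondominant"] = float(np.clip(_round_half(sev_nd * 4), 0, 4))
        mean_sev = 0.5 * (sev_d + sev_nd)
        out["bars_total"] = float(np.clip(round(mean_sev * 30 + rng.normal(0, 1.5)), 0, 30))
    elif group == "parkinsonism":
        out["updrs_arm_dominant"] = float(np.clip(round(sev_d * 12), 0, 12))
        out["updrs_arm_nondominant"] = float(np.clip(round(sev_nd * 12), 0, 12))
        mean_sev = 0.5 * (sev_d + sev_nd)
        out["updrs_total"] = float(np.clip(round(mean_sev * 48 + rng.normal(0, 3)), 0, 108))
    return out


def generate_cohort(spec: CohortSpec | None = None) -> CohortDataset:
    """Generate a full two-handed cohort, reproducible from ``spec.seed``.

    Subjects are drawn per group; a configured number of videos are repeat
    visits (the repeat subjects contribute two sessions with the same
    subject-level phenotype).  Severity labels derive deterministically
    from the per-hand generative parameters.
    """
    spec = spec or CohortSpec()
    spec.validate()
    master = np.random.SeedSequence(spec.seed)
    group_seeds = master.spawn(len(spec.groups))

    recordings: dict[tuple[str, str], LandmarkRecording] = {}
    truths: dict[tuple[str, str], GroundTruth] = {}
    rows = []

    for (group, g), gseed in zip(spec.groups.items(), group_seeds):
        if g.n_videos == 0:
            continue
        rng = np.random.default_rng(gseed)
        n_subjects = g.n_videos - g.n_repeat_videos
        if n_subjects <= 0:
            raise ParameterError(f"group {group}: repeats exceed videos")
        for si in range(n_subjects):
            subject_id = f"{group[:3]}{si:03d}"
            age = float(np.clip(rng.normal(g.age_mean, g.age_sd), *g.age_range))
            sp = _subject_params(g, rng)
            n_visits = 2 if si < g.n_repeat_videos else 1
            for visit in range(n_visits):
                session_id = f"{subject_id}_v{visit}"
                hand_params = {
                    "dominant": _hand_variant(sp, spec.hand_jitter_frac, rng),
                    "nondominant": _hand_variant(sp, spec.hand_jitter_frac, rng),
                }
                sev = {
                    h: severity_from_params(p, group, spec.severity_coeffs)
                    for h, p in hand_params.items()
                }
                for hand_name, p in hand_params.items():
                    rec_seed = int(rng.integers(0, 2**31 - 1))
                    rec, gt = generate_tapping_recording(
                        p, rec_seed, hand=hand_name, subject_id=subject_id,
                        session_id=session_id, group=group,
                        severity_coeffs=spec.severity_coeffs,
                    )
                    recordings[(session_id, hand_name)] = rec
                    truths[(session_id, hand_name)] = gt
                scores = _clinical_scores(group, sev["dominant"], sev["nondominant"], rng)
                rows.append(
                    dict(
                        session_id=session_id, subject_id=subject_id, group=group,
                        visit=visit, age=age,
                        severity_dominant=sev["dominant"],
                        severity_nondominant=sev["nondominant"],
                        **scores,
                    )
                )

    manifest = pd.DataFrame(rows)
    return CohortDataset(recordings=recordings, ground_truth=truths, manifest=manifest)


def small_cohort_spec(
    n_ataxia: int,
    n_parkinsonism: int,
    n_control: int,
    seed: int = 0,
    repeat_fraction: float = 0.2,
) -> CohortSpec:
    """Convenience spec with scaled-down per-group counts."""
    groups = {}
    for name, n in (
        ("ataxia", n_ataxia),
        ("parkinsonism", n_parkinsonism),
        ("control", n_control),
    ):
        if n == 0:
            continue
        base = _default_groups()[name]
        groups[name] = replace(base, n_videos=n, n_repeat_videos=int(n * repeat_fraction))
    return CohortSpec(groups=groups, seed=seed)
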