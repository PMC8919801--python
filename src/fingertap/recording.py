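"""Core data containers: landmark recordings, tapping signals, tap events.

A :class:`LandmarkRecording` holds the per-frame 2-D positions of the three
hand landmarks a markerless pose tracker emits (index fingertip, thumb tip,
wrist) for one hand of one session.  Downstream stages reduce it to a
:class:`TappingSignal` — the cleaned, filtered, z-scored index–thumb
distance with its first three time derivatives — and then to
:class:`TapEvents`, the alternating peak/trough sequence of the tap cycles.

Missing samples are represented as NaN; a confidence below the configured
floor is treated as missing at preprocessing time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

LANDMARKS = ("index_tip", "thumb_tip", "wrist")
SUPPORTED_RATES = (30, 60)


@dataclass
class LandmarkRecording:
    """Raw per-frame 2-D landmark coordinates for one hand.

    Attributes
    ----------
    fs : int
        Sampling rate in Hz; 30 or 60.
    frames : np.ndarray
        Strictly increasing sample indices, shape (n,).
    xy : dict[str, np.ndarray]
        Per-landmark (n, 2) coordinate arrays in pixels; NaN marks a
        missing sample.
    confidence : dict[str, np.ndarray]
        Per-landmark tracker confidence in [0, 1].
    hand : str
        "dominant" or "nondominant".
    subject_id, session_id : str
        Cohort bookkeeping.
    segment : tuple[int, int] | None
        Optional (start, end) sample annotation of the task window,
        end-exclusive.
    """

    fs: int
    frames: np.ndarray
    xy: dict[str, np.ndarray]
    confidence: dict[str, np.ndarray]
    hand: str = "dominant"
    subject_id: str = ""
    session_id: str = ""
    segment: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.fs not in SUPPORTED_RATES:
            raise ValidationError(f"fs must be one of {SUPPORTED_RATES}, got {self.fs}")
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 1 or np.any(np.diff(self.frames) <= 0):
            raise ValidationError("frames must be a strictly increasing 1-D array")
        n = len(self.frames)
        for name in LANDMARKS:
            if name not in self.xy:
                raise ValidationError(f"missing landmark {name!r}")
            arr = np.asarray(self.xy[name], dtype=float)
            if arr.shape != (n, 2):
                raise ValidationError(f"landmark {name!r} must have shape ({n}, 2)")
            self.xy[name] = arr

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, landmark, x, y, confidence."""
        rows = []
        for name in LANDMARKS:
            df = pd.DataFrame(
                {
                    "frame": self.frames,
                    "landmark": name,
                    "x": self.xy[name][:, 0],
                    "y": self.xy[name][:, 1],
                    "confidence": self.confidence[name],
                }
            )
            rows.append(df)
        return pd.concat(rows, ignore_index=True).sort_values(
            ["frame", "landmark"], kind="stable", ignore_index=True
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        fs: int,
        hand: str = "dominant",
        subject_id: str = "",
        session_id: str = "",
        segment: tuple[int, int] | None = None,
    ) -> "LandmarkRecording":
        """Build a recording from the long (frame, landmark, x, y, confidence) layout."""
        required = {"frame", "landmark", "x", "y"}
        if not required.issubset(df.columns):
            raise ValidationError(f"landmark table needs columns {sorted(required)}")
        frames = np.sort(df["frame"].unique())
        xy: dict[str, np.ndarray] = {}
        conf: dict[str, np.ndarray] = {}
        for name in LANDMARKS:
            sub = df[df["landmark"] == name].set_index("frame")
            sub = sub.reindex(frames)
            xy[name] = sub[["x", "y"]].to_numpy(dtype=float)
            if "confidence" in sub.columns:
                conf[name] = sub["confidence"].to_numpy(dtype=float)
            else:
                conf[name] = np.ones(len(frames))
        return cls(
            fs=fs,
            frames=frames,
            xy=xy,
            confidence=conf,
            hand=hand,
            subject_id=subject_id,
            session_id=session_id,
            segment=segment,
        )

    @classmethod
    def read_csv(cls, path: str | Path, fs: int, **kw) -> "LandmarkRecording":
        return cls.from_frame(pd.read_csv(path), fs=fs, **kw)


@dataclass
class QCReport:
    """Per-recording quality-control counters."""

    outlier_count: int = 0
    interpolated_count: int = 0
    unrecoverable_gap_count: int = 0
    unrecoverable_sample_count: int = 0
    trimmed_samples: int = 0

    def to_dict(self) -> dict:
        return {k: int(v) for k, v in self.__dict__.items()}


@dataclass
class TappingSignal:
    """Cleaned, filtered, z-scored index–thumb distance with derivatives.

    ``amplitude`` is unitless (z-units); ``velocity``, ``acceleration`` and
    ``jerk`` are the first three central-difference time derivatives in
    z-units per s, s^2 and s^3.  ``fs`` is always 30 Hz after preprocessing.
    """

    fs: int
    amplitude: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    jerk: np.ndarray
    qc: QCReport = field(default_factory=QCReport)
    hand: str = "dominant"
    subject_id: str = ""
    session_id: str = ""

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.amplitude)) / self.fs

    @property
    def n(self) -> int:
        return len(self.amplitude)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "amplitude": self.amplitude,
                "velocity": self.velocity,
                "acceleration": self.acceleration,
                "jerk": self.jerk,
            }
        )

    def write_csv(self, path: str | Path, qc_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if qc_path is not None:
            Path(qc_path).write_text(json.dumps(self.qc.to_dict(), indent=2))

    @classmethod
    def read_csv(cls, path: str | Path, fs: int = 30, **kw) -> "TappingSignal":
        df = pd.read_csv(path)
        return cls(
            fs=fs,
            amplitude=df["amplitude"].to_numpy(),
            velocity=df["velocity"].to_numpy(),
            acceleration=df["acceleration"].to_numpy(),
            jerk=df["jerk"].to_numpy(),
            **kw,
        )


@dataclass
class TapEvents:
    """Alternating peak/trough sequence for one tapping signal.

    The sequence starts and ends on a peak; trough k sits between peaks k
    and k+1, so ``len(trough_times) == len(peak_times) - 1``.  Times are in
    seconds, amplitudes in z-units.
    """

    peak_times: np.ndarray
    peak_amps: np.ndarray
    trough_times: np.ndarray
    trough_amps: np.ndarray

    def __post_init__(self) -> None:
        for name in ("peak_times", "peak_amps", "trough_times", "trough_amps"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)

    @property
    def n_troughs(self) -> int:
        return len(self.trough_times)

    @property
    def n_cycles(self) -> int:
        """Number of trough-to-trough cycles."""
        return max(self.n_troughs - 1, 0)

    def interleaved(self) -> tuple[np.ndarray, np.ndarray]:
        """All events merged in time order: (times, amplitudes)."""
        t = np.concatenate([self.peak_times, self.trough_times])
        a = np.concatenate([self.peak_amps, self.trough_amps])
        order = np.argsort(t)
        return t[order], a[order]


@dataclass
class TapCycleFit:
    """Quadratic parameterization of one trough-to-trough cycle.

    Coefficients of amplitude ~ a*tau^2 + b*tau + c on normalized cycle
    time tau in [0, 1]; ``a`` is the curvature coefficient.
    """

    a: float
    b: float
    c: float
    rss: float
    t_start: float
    t_end: float
    n_samples: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start
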