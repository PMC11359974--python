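"""Core domain types for dynamometry trial data and reliability matrices.

The unit of raw data is a :class:`TrialRecording` — one maximal voluntary
contraction (MVC) with a force trace and, usually, a surface-EMG trace,
both uniformly sampled (nominally 1961 Hz). The unit of reliability
analysis is an :class:`OutcomeMatrix` — an n-subjects x 2-sessions table
of one aggregated outcome.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class Units(str, enum.Enum):
    """Physical units of a sampled signal."""

    NEWTON = "N"
    VOLT = "V"


class Aggregation(str, enum.Enum):
    """How the three trials of one session are reduced to a single value."""

    MEAN3 = "mean3"
    BEST3 = "best3"


@dataclass
class SignalTrace:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    samples : array-like of float
        Sample values in `units`. No missing values allowed.
    rate_hz : float
        Sampling rate in Hz; must be positive.
    units : Units
        ``Units.NEWTON`` for force, ``Units.VOLT`` for EMG.

    Notes
    -----
    At least one second of data is required so that a 500 ms
    pre-contraction baseline window always fits.
    """

    samples: np.ndarray
    rate_hz: float
    units: Units

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.units = Units(self.units)
        if self.samples.ndim != 1:
            raise ValueError("SignalTrace samples must be 1-D")
        if not np.isfinite(self.rate_hz) or self.rate_hz <= 0:
            raise ValueError("rate_hz must be a positive finite number")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("SignalTrace contains non-finite samples")
        if self.samples.size < self.rate_hz * 1.0:
            raise ValueError(
                "SignalTrace must hold at least 1 s of data "
                f"({self.samples.size} samples at {self.rate_hz} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds; sample 0 is t = 0."""
        return np.arange(self.samples.size) / self.rate_hz

    def with_samples(self, samples: np.ndarray) -> "SignalTrace":
        """Copy of this trace with new sample values (same rate/units)."""
        return SignalTrace(np.asarray(samples, float), self.rate_hz, self.units)


@dataclass
class TrialRecording:
    """One MVC trial: paired force and (optional) EMG traces with identifiers."""

    subject_id: str
    session: int
    trial: int
    force: SignalTrace
    emg: Optional[SignalTrace] = None

    def __post_init__(self) -> None:
        if self.session not in (1, 2):
            raise ValueError(f"session must be 1 or 2, got {self.session}")
        if self.trial not in (1, 2, 3):
            raise ValueError(f"trial must be 1, 2 or 3, got {self.trial}")
        if self.force.units is not Units.NEWTON:
            raise ValueError("force trace must be in newtons")
        if self.emg is not None:
            if self.emg.units is not Units.VOLT:
                raise ValueError("emg trace must be in volts")
            if self.emg.rate_hz != self.force.rate_hz:
                raise ValueError("force and emg must share the sampling rate")
            if self.emg.n_samples != self.force.n_samples:
                raise ValueError("force and emg must share the duration")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.subject_id, self.session, self.trial)


@dataclass
class TrialOutcomes:
    """The scalar outcomes extracted from one trial.

    mvc_n
        Peak force minus mean baseline (N).
    rfd200_n_per_s
        Rate of force development over the first 200 ms after onset (N/s).
    t90_s
        Time from onset to first reaching 90% of the trial's MVC (s).
    peak_emg_rms_v
        Peak of the EMG RMS envelope within +-1 s of the force peak (V);
        ``None`` when the trial has no EMG.
    onset_s
        Detected contraction onset, seconds from trace start.
    """

    mvc_n: float
    rfd200_n_per_s: float
    t90_s: float
    onset_s: float
    peak_emg_rms_v: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("mvc_n", "rfd200_n_per_s", "t90_s", "onset_s"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.mvc_n < 0:
            raise ValueError("mvc_n must be >= 0")
        if self.t90_s < 0:
            raise ValueError("t90_s must be >= 0")
        if self.peak_emg_rms_v is not None and (
            not np.isfinite(self.peak_emg_rms_v) or self.peak_emg_rms_v < 0
        ):
            raise ValueError("peak_emg_rms_v must be finite and >= 0")


@dataclass
class StudyDataset:
    """All trials of a two-session study plus free-form manifest metadata."""

    trials: list[TrialRecording]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int]] = set()
        for t in self.trials:
            if t.key in seen:
                raise ValueError(f"duplicate trial {t.key}")
            seen.add(t.key)

    @property
    def subject_ids(self) -> list[str]:
        out: list[str] = []
        for t in self.trials:
            if t.subject_id not in out:
                out.append(t.subject_id)
        return out

    def trials_for(self, subject_id: str, session: int) -> list[TrialRecording]:
        return sorted(
            (t for t in self.trials if t.subject_id == subject_id and t.session == session),
            key=lambda t: t.trial,
        )


@dataclass
class OutcomeMatrix:
    """n-subjects x 2-sessions table of one aggregated outcome."""

    values: np.ndarray
    outcome_name: str
    aggregation: Aggregation
    subject_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.aggregation = Aggregation(self.aggregation)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("OutcomeMatrix values must be n x 2")
        if self.values.shape[0] < 2:
            raise ValueError("OutcomeMatrix needs at least 2 subjects")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("OutcomeMatrix must have no missing cells")
        if self.subject_ids is not None and len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length must match number of rows")

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    def with_values(self, values: np.ndarray) -> "OutcomeMatrix":
        return OutcomeMatrix(values, self.outcome_name, self.aggregation, self.subject_ids)
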