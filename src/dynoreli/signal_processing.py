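"""Trace conditioning and outcome extraction for isometric MVC trials.

Processing chain for one trial:

1. force: zero-phase 4th-order Butterworth low-pass at 15 Hz;
2. contraction onset: first sample exceeding the 500 ms baseline mean by
   3 baseline SDs and staying above threshold for a debounce hold;
3. MVC = peak force - baseline mean;
4. RFD200 = baseline-corrected force 200 ms after onset, divided by 0.2 s;
5. t90 = time from onset to first reaching 90% of MVC;
6. EMG: zero-phase band-pass 10-500 Hz, moving-RMS envelope, peak of the
   envelope within +-1 s of the force peak.

All times are seconds from trace start; sample 0 is t = 0. Force values are
read at the nearest sample (no interpolation): at 1961 Hz the quantisation
is ~0.5 ms, negligible against between-session measurement error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.signal

from .types import SignalTrace, TrialOutcomes, TrialRecording, Units

__all__ = [
    "OnsetSpec",
    "OnsetResult",
    "lowpass_force",
    "bandpass_emg",
    "detect_onset",
    "compute_mvc",
    "compute_rfd200",
    "compute_t90",
    "emg_rms_envelope",
    "compute_peak_emg",
    "extract_trial_outcomes",
]

FORCE_LOWPASS_HZ = 15.0
EMG_BAND_HZ = (10.0, 500.0)
FILTER_ORDER = 4
RFD_WINDOW_S = 0.200
EMG_SEARCH_HALF_WIDTH_S = 1.0
DEFAULT_RMS_WINDOW_S = 0.050


@dataclass(frozen=True)
class OnsetSpec:
    """Parameters of the baseline-threshold onset detector.

    baseline_window_s
        Length of the pre-contraction window used for the baseline mean and
        SD (default 0.5 s).
    k_sd
        Threshold in baseline SDs above the baseline mean (default 3).
    min_hold_s
        Debounce: the signal must stay above threshold this long for the
        crossing to count as onset (default 25 ms). Replaces the visual
        confirmation step a human rater would perform.
    """

    baseline_window_s: float = 0.5
    k_sd: float = 3.0
    min_hold_s: float = 0.025

    def __post_init__(self) -> None:
        if self.baseline_window_s <= 0:
            raise ValueError("baseline_window_s must be > 0")
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")
        if self.min_hold_s < 0:
            raise ValueError("min_hold_s must be >= 0")


@dataclass(frozen=True)
class OnsetResult:
    """Detected onset plus the baseline statistics that defined it."""

    onset_s: float
    onset_index: int
    baseline_mean: float
    baseline_sd: float
    threshold: float


def _sosfiltfilt(sos: np.ndarray, trace: SignalTrace) -> SignalTrace:
    padlen = 3 * (2 * sos.shape[0] + 1)
    if trace.n_samples <= 3 * padlen:
        raise ValueError(
            f"trace too short to filter: {trace.n_samples} samples, "
            f"need more than {3 * padlen}"
        )
    return trace.with_samples(scipy.signal.sosfiltfilt(sos, trace.samples))


def lowpass_force(trace: SignalTrace) -> SignalTrace:
    """Zero-phase 4th-order Butterworth low-pass at 15 Hz.

    Forward-backward application doubles the attenuation (the magnitude
    response is squared) and cancels the phase shift, so peak timing is
    preserved.
    """
    if trace.rate_hz <= 2 * FORCE_LOWPASS_HZ:
        raise ValueError("sampling rate must exceed 30 Hz for the 15 Hz low-pass")
    sos = scipy.signal.butter(FILTER_ORDER, FORCE_LOWPASS_HZ, "lowpass", fs=trace.rate_hz, output="sos")
    return _sosfiltfilt(sos, trace)


def bandpass_emg(trace: SignalTrace) -> SignalTrace:
    """Zero-phase 4th-order Butterworth band-pass, 10-500 Hz."""
    if trace.rate_hz <= 1000.0:
        raise ValueError(
            "EMG sampling rate must exceed 1000 Hz so the 500 Hz band edge is below Nyquist"
        )
    sos = scipy.signal.butter(FILTER_ORDER, EMG_BAND_HZ, "bandpass", fs=trace.rate_hz, output="sos")
    return _sosfiltfilt(sos, trace)


def detect_onset(force: SignalTrace, spec: OnsetSpec = OnsetSpec()) -> OnsetResult:
    """Find contraction onset by the baseline-plus-k-SD threshold rule.

    The baseline mean ``m`` and SD ``s`` come from the first
    ``baseline_window_s`` of the trace (which must be pre-contraction).
    Onset is the first sample strictly above ``m + k_sd * s`` that stays
    above threshold for ``min_hold_s``.
    """
    x = force.samples
    n_base = int(round(spec.baseline_window_s * force.rate_hz))
    if n_base < 2:
        raise ValueError("baseline window holds fewer than 2 samples")
    if n_base >= x.size:
        raise ValueError("baseline window exceeds the trace")
    baseline = x[:n_base]
    m = float(baseline.mean())
    s = float(baseline.std(ddof=1))
    threshold = m + spec.k_sd * s

    above = x > threshold
    hold = max(1, int(round(spec.min_hold_s * force.rate_hz)))
    if hold > 1:
        runs = np.convolve(above.astype(np.int32), np.ones(hold, dtype=np.int32), mode="valid")
        sustained = runs == hold
    else:
        sustained = above
    if not sustained.any():
        raise ValueError("no onset detected: no threshold crossing sustained long enough")
    idx = int(np.argmax(sustained))
    return OnsetResult(
        onset_s=idx / force.rate_hz,
        onset_index=idx,
        baseline_mean=m,
        baseline_sd=s,
        threshold=threshold,
    )


def compute_mvc(force: SignalTrace, baseline_mean: float) -> tuple[float, float]:
    """MVC amplitude: peak force minus baseline mean.

    Returns ``(mvc_n, peak_time_s)``; the peak time anchors the +-1 s EMG
    search window. A peak landing inside the baseline window triggers an
    artefact warning but is still returned.
    """
    peak_idx = int(np.argmax(force.samples))
    mvc = float(force.samples[peak_idx]) - baseline_mean
    peak_time = peak_idx / force.rate_hz
    return mvc, peak_time


def compute_rfd200(
    force: SignalTrace,
    onset_s: float,
    baseline_mean: float,
    *,
    baseline_correct: bool = True,
) -> float:
    """Rate of force development over the fixed 0-200 ms window after onset.

    ``(F(onset + 0.2 s) - baseline_mean) / 0.2`` with F read at the nearest
    sample. ``baseline_correct=False`` divides the uncorrected force
    instead, for comparison with pipelines that skip the offset removal.
    """
    idx = int(round((onset_s + RFD_WINDOW_S) * force.rate_hz))
    if idx >= force.n_samples:
        raise ValueError("trace ends before onset + 200 ms")
    f = float(force.samples[idx])
    if baseline_correct:
        f -= baseline_mean
    return f / RFD_WINDOW_S


def compute_t90(force: SignalTrace, onset_s: float, baseline_mean: float, mvc_n: float) -> float:
    """Time from onset to first reaching 90% of the trial's MVC."""
    if mvc_n <= 0:
        raise ValueError("mvc_n must be > 0")
    onset_idx = int(round(onset_s * force.rate_hz))
    rel = force.samples[onset_idx:] - baseline_mean
    hits = np.nonzero(rel >= 0.9 * mvc_n)[0]
    if hits.size == 0:
        # only possible when the trace max precedes the detected onset,
        # i.e. an artefact dominated the recording
        raise ValueError("90% of MVC never reached after onset (artefact peak before onset?)")
    return float(hits[0] / force.rate_hz)


def emg_rms_envelope(emg: SignalTrace, window_s: float = DEFAULT_RMS_WINDOW_S) -> SignalTrace:
    """Centred moving-RMS envelope; edges average over the available samples."""
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    w = int(round(window_s * emg.rate_hz))
    if w < 1:
        raise ValueError("RMS window shorter than one sample")
    if w > emg.n_samples:
        raise ValueError("RMS window longer than the trace")
    x2 = emg.samples**2
    kernel = np.ones(w)
    sums = np.convolve(x2, kernel, mode="same")
    counts = np.convolve(np.ones_like(x2), kernel, mode="same")
    return emg.with_samples(np.sqrt(sums / counts))


def compute_peak_emg(emg_env: SignalTrace, force_peak_time: float) -> float:
    """Peak of the RMS envelope within +-1 s of the force peak (clipped)."""
    lo = int(np.ceil((force_peak_time - EMG_SEARCH_HALF_WIDTH_S) * emg_env.rate_hz))
    hi = int(np.floor((force_peak_time + EMG_SEARCH_HALF_WIDTH_S) * emg_env.rate_hz))
    lo = max(lo, 0)
    hi = min(hi, emg_env.n_samples - 1)
    if hi < lo:
        raise ValueError("EMG search window does not intersect the recording")
    return float(emg_env.samples[lo : hi + 1].max())


def extract_trial_outcomes(
    trial: TrialRecording,
    spec: OnsetSpec = OnsetSpec(),
    *,
    rms_window_s: float = DEFAULT_RMS_WINDOW_S,
    mvc_raw: bool = False,
    rfd_baseline_correct: bool = True,
) -> TrialOutcomes:
    """Run the full conditioning-and-extraction chain on one trial.

    ``mvc_raw=True`` computes MVC (and its peak time) on the unfiltered
    force trace, mirroring workflows where peak amplitude is read off the
    acquisition software while the rate measures use the filtered export;
    by default a single conditioning path is used. EMG outcomes are absent
    when the trial has no EMG.
    """
    try:
        filtered = lowpass_force(trial.force)
        onset = detect_onset(filtered, spec)
        mvc_src = trial.force if mvc_raw else filtered
        mvc, peak_time = compute_mvc(mvc_src, onset.baseline_mean)
        if peak_time < onset.onset_s:
            warnings.warn(
                f"trial {trial.key}: force peak precedes detected onset "
                "(possible artefact)",
                stacklevel=2,
            )
        rfd = compute_rfd200(
            filtered, onset.onset_s, onset.baseline_mean, baseline_correct=rfd_baseline_correct
        )
        t90 = compute_t90(filtered, onset.onset_s, onset.baseline_mean, mvc)

        peak_emg: Optional[float] = None
        if trial.emg is not None:
            env = emg_rms_envelope(bandpass_emg(trial.emg), rms_window_s)
            peak_emg = compute_peak_emg(env, peak_time)
    except ValueError as exc:
        raise ValueError(f"trial {trial.key}: {exc}") from exc

    return TrialOutcomes(
        mvc_n=mvc,
        rfd200_n_per_s=rfd,
        t90_s=t90,
        onset_s=onset.onset_s,
        peak_emg_rms_v=peak_emg,
    )
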