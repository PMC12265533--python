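"""Rule-based artifact rejection for epoched EEG.

Detector suite (thresholds as used in the emulated recording pipeline):

* EOG absolute voltage > 50 uV; EOG step > 30 uV (100-ms window, 10-ms
  steps);
* gaze step > 0.5 deg (100-ms window, 10-ms steps), used when eye-tracking
  channels are present, with EOG as the fallback;
* drift: fitted line with total voltage change > 75 uV and R^2 >= 0.3;
* peak-to-peak > 75 uV (200-ms window, 100-ms steps);
* absolute voltage > +/-100 uV in any EEG channel;
* EEG step > 60 uV (150-ms window, 10-ms steps);
* flatline (zero variance over a configurable span, default whole epoch).

Step detectors use the half-window mean-difference form: within each
window the absolute difference between the mean of the second half and the
mean of the first half is compared to the threshold.  Windows sit on
sample indices with a half-open ``[start, start + length)`` convention;
partial trailing windows are skipped.  A trial is rejected when any
detector flags it; participants with > 30% of trials rejected are
excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from wmcda.cda.epochs import EOG_CHANNELS, GAZE_CHANNELS, EpochSet

__all__ = [
    "detect_eog",
    "detect_gaze",
    "detect_drift",
    "detect_p2p",
    "detect_abs_and_steps",
    "reject_and_exclude",
    "ArtifactReport",
    "DETECTOR_NAMES",
]

DETECTOR_NAMES = (
    "eog_abs", "eog_step", "gaze", "drift", "p2p", "abs_volt", "eeg_step", "flatline",
)

#: Participants with a rejection proportion above this are excluded.
EXCLUSION_RATE = 0.30


def _win_samples(epochs: EpochSet, window_ms: float, step_ms: float) -> tuple[int, int]:
    win = int(round(window_ms * epochs.sfreq / 1000.0))
    step = max(1, int(round(step_ms * epochs.sfreq / 1000.0)))
    if win < 2 or win > epochs.n_samples:
        raise ValueError(f"window of {window_ms} ms invalid for this epoch length")
    return win, step


def _step_amplitude(data: np.ndarray, win: int, step: int) -> np.ndarray:
    """Max half-window mean difference over sliding windows.

    ``data`` is (..., samples); returns (...,) with the maximum over
    windows and leading channel axes collapsed by the caller.
    """
    views = sliding_window_view(data, win, axis=-1)[..., ::step, :]
    half = win // 2
    first = views[..., :half].mean(axis=-1)
    second = views[..., half : 2 * half].mean(axis=-1)
    return np.abs(second - first).max(axis=-1)


def _p2p_amplitude(data: np.ndarray, win: int, step: int) -> np.ndarray:
    views = sliding_window_view(data, win, axis=-1)[..., ::step, :]
    return (views.max(axis=-1) - views.min(axis=-1)).max(axis=-1)


def detect_eog(
    epochs: EpochSet,
    abs_threshold: float = 50.0,
    step_threshold: float = 30.0,
    window_ms: float = 100.0,
    step_ms: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """EOG absolute-voltage and step detectors.

    Returns ``(abs_flags, step_flags)`` boolean arrays over trials.
    Raises when neither EOG nor gaze channels exist (no ocular measure at
    all).
    """
    have_eog = epochs.has_channels(EOG_CHANNELS)
    if not have_eog:
        if epochs.has_channels(GAZE_CHANNELS):
            n = epochs.n_trials
            return np.zeros(n, bool), np.zeros(n, bool)
        raise ValueError("no EOG channels and no gaze channels: cannot screen ocular artifacts")
    idx = epochs.channel_index(EOG_CHANNELS)
    eog = epochs.data[:, idx, :]
    abs_flags = (np.abs(eog) > abs_threshold).any(axis=(1, 2))
    win, step = _win_samples(epochs, window_ms, step_ms)
    step_flags = (_step_amplitude(eog, win, step) > step_threshold).any(axis=1)
    return abs_flags, step_flags


def detect_gaze(
    epochs: EpochSet,
    threshold_deg: float = 0.5,
    window_ms: float = 100.0,
    step_ms: float = 10.0,
) -> np.ndarray | None:
    """Step-style detector on gaze x/y; ``None`` when gaze is absent."""
    if not epochs.has_channels(GAZE_CHANNELS):
        warnings.warn("gaze channels absent; gaze detector skipped (EOG fallback applies)")
        return None
    idx = epochs.channel_index(GAZE_CHANNELS)
    gaze = epochs.data[:, idx, :]
    win, step = _win_samples(epochs, window_ms, step_ms)
    return (_step_amplitude(gaze, win, step) > threshold_deg).any(axis=1)


def detect_drift(
    epochs: EpochSet,
    change_threshold: float = 75.0,
    min_r2: float = 0.3,
) -> np.ndarray:
    """Linear-trend detector on EEG channels.

    A least-squares line is fitted per channel per epoch; the trial is
    flagged when the magnitude of the total fitted voltage change across
    the epoch exceeds the threshold *and* the fit explains at least
    ``min_r2`` of the variance.
    """
    idx = epochs.channel_index(epochs.eeg_channels)
    y = epochs.data[:, idx, :].astype(float)
    n = y.shape[-1]
    x = np.arange(n, dtype=float)
    x_c = x - x.mean()
    var_x = (x_c**2).sum()
    y_c = y - y.mean(axis=-1, keepdims=True)
    slope = (y_c * x_c).sum(axis=-1) / var_x
    total_change = slope * (n - 1)
    ss_tot = (y_c**2).sum(axis=-1)
    ss_fit = slope**2 * var_x
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, ss_fit / ss_tot, 0.0)
    return ((np.abs(total_change) > change_threshold) & (r2 >= min_r2)).any(axis=1)


def detect_p2p(
    epochs: EpochSet,
    threshold: float = 75.0,
    window_ms: float = 200.0,
    step_ms: float = 100.0,
) -> np.ndarray:
    """Peak-to-peak detector on EEG channels (max - min per window)."""
    idx = epochs.channel_index(epochs.eeg_channels)
    win, step = _win_samples(epochs, window_ms, step_ms)
    return (_p2p_amplitude(epochs.data[:, idx, :], win, step) > threshold).any(axis=1)


def detect_abs_and_steps(
    epochs: EpochSet,
    abs_threshold: float = 100.0,
    step_threshold: float = 60.0,
    step_window_ms: float = 150.0,
    step_step_ms: float = 10.0,
    flatline_span_ms: float | None = None,
) -> dict[str, np.ndarray]:
    """EEG absolute-voltage, step, and flatline detectors.

    ``flatline_span_ms`` of ``None`` checks zero variance over the whole
    epoch; otherwise any sliding span of that length with zero variance
    flags the trial.
    """
    idx = epochs.channel_index(epochs.eeg_channels)
    eeg = epochs.data[:, idx, :]
    abs_flags = (np.abs(eeg) > abs_threshold).any(axis=(1, 2))
    win, step = _win_samples(epochs, step_window_ms, step_step_ms)
    step_flags = (_step_amplitude(eeg, win, step) > step_threshold).any(axis=1)
    if flatline_span_ms is None:
        flat = (eeg.var(axis=-1) == 0.0).any(axis=1)
    else:
        fwin, _ = _win_samples(epochs, flatline_span_ms, flatline_span_ms)
        views = sliding_window_view(eeg, fwin, axis=-1)
        flat = (views.var(axis=-1) == 0.0).any(axis=(1, 2))
    return {"abs_volt": abs_flags, "eeg_step": step_flags, "flatline": flat}


@dataclass
class ArtifactReport:
    """Per-trial detector flags and per-participant rejection bookkeeping."""

    flags: pd.DataFrame              # trials x detectors (bool)
    rejected: np.ndarray             # union of flags
    participant_rates: pd.Series     # rejection proportion per participant
    excluded_participants: list      # rate > EXCLUSION_RATE

    @property
    def rejection_rate(self) -> float:
        return float(self.rejected.mean())

    def to_json_dict(self) -> dict:
        return {
            "n_trials": int(len(self.rejected)),
            "n_rejected": int(self.rejected.sum()),
            "rejection_rate": self.rejection_rate,
            "per_detector": {c: int(self.flags[c].sum()) for c in self.flags.columns},
            "participant_rates": {str(k): float(v) for k, v in self.participant_rates.items()},
            "excluded_participants": [str(p) for p in self.excluded_participants],
        }


def reject_and_exclude(
    epochs: EpochSet,
    exclusion_rate: float = EXCLUSION_RATE,
) -> tuple[ArtifactReport, EpochSet, list]:
    """Run the full detector suite, reject trials, exclude participants.

    Returns ``(report, retained_epochs, retained_participants)`` where
    retained epochs exclude both flagged trials and all trials of excluded
    participants (rejection rate > ``exclusion_rate``).  Raises when every
    participant is excluded.
    """
    n = epochs.n_trials
    flags = pd.DataFrame(index=range(n))
    eog_abs, eog_step = detect_eog(epochs)
    flags["eog_abs"] = eog_abs
    flags["eog_step"] = eog_step
    gaze = detect_gaze(epochs) if epochs.has_channels(GAZE_CHANNELS) else None
    flags["gaze"] = gaze if gaze is not None else np.zeros(n, bool)
    flags["drift"] = detect_drift(epochs)
    flags["p2p"] = detect_p2p(epochs)
    flags.loc[:, ["abs_volt", "eeg_step", "flatline"]] = pd.DataFrame(
        detect_abs_and_steps(epochs), index=flags.index
    )
    rejected = flags.to_numpy().any(axis=1)

    participants = epochs.metadata["participant"]
    rates = pd.Series(rejected).groupby(participants.reset_index(drop=True)).mean()
    excluded = [p for p, r in rates.items() if r > exclusion_rate]
    retained_participants = [p for p in rates.index if p not in excluded]
    if not retained_participants:
        raise ValueError("all participants exceeded the rejection-rate exclusion threshold")

    keep = (~rejected) & (~participants.isin(excluded).to_numpy())
    report = ArtifactReport(
        flags=flags.astype(bool),
        rejected=rejected,
        participant_rates=rates,
        excluded_participants=excluded,
    )
    return report, epochs.select(keep), retained_participants
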