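"""Epoched multichannel ERP data container and directory I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from wmcda._utils import CDA_CHANNELS

__all__ = ["EpochSet"]

EOG_CHANNELS = ("VEOG", "HEOG")
GAZE_CHANNELS = ("GAZE_X", "GAZE_Y")


@dataclass
class EpochSet:
    """Trials x channels x samples tensor with per-trial metadata.

    Attributes
    ----------
    data : ndarray (n_trials, n_channels, n_samples)
        Voltages in microvolts (gaze channels, if present, in degrees).
    sfreq : float
        Sampling rate in Hz.
    tmin_ms : float
        Time of the first sample relative to memory-array onset (ms).
    channels : list of str
    metadata : DataFrame with one row per trial; expected columns include
        ``participant``, ``cue_side`` ('left'/'right'), ``set_size``,
        ``stim_type``.
    """

    data: np.ndarray
    sfreq: float
    tmin_ms: float
    channels: list
    metadata: pd.DataFrame

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel count does not match data")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows do not match trial count")
        self.metadata = self.metadata.reset_index(drop=True)

    # ------------------------------------------------------------------ #
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.sfreq

    def channel_index(self, names) -> np.ndarray:
        missing = [ch for ch in names if ch not in self.channels]
        if missing:
            raise ValueError(f"missing channels {missing}; available: {self.channels}")
        return np.array([self.channels.index(ch) for ch in names])

    @property
    def eeg_channels(self) -> list:
        aux = set(EOG_CHANNELS) | set(GAZE_CHANNELS)
        return [ch for ch in self.channels if ch not in aux]

    def has_channels(self, names) -> bool:
        return all(ch in self.channels for ch in names)

    def sample_window(self, start_ms: float, end_ms: float) -> tuple[int, int]:
        """Half-open [start, end) sample-index window for a time range in ms."""
        i0 = int(round((start_ms - self.tmin_ms) * self.sfreq / 1000.0))
        i1 = int(round((end_ms - self.tmin_ms) * self.sfreq / 1000.0))
        if i0 < 0 or i1 > self.n_samples or i0 >= i1:
            raise ValueError(f"window {start_ms}..{end_ms} ms outside the epoch")
        return i0, i1

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            sfreq=self.sfreq,
            tmin_ms=self.tmin_ms,
            channels=list(self.channels),
            metadata=self.metadata.loc[mask].reset_index(drop=True),
        )

    # ------------------------------------------------------------------ #
    def save(self, directory) -> None:
        """Write the epoch set as a directory: tensor (.npy), channels.json,
        trials.csv."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "epochs.npy", self.data)
        (d / "channels.json").write_text(
            json.dumps({"channels": list(self.channels), "sfreq": self.sfreq,
                        "tmin_ms": self.tmin_ms})
        )
        self.metadata.to_csv(d / "trials.csv", index=False)

    @classmethod
    def load(cls, directory) -> "EpochSet":
        d = Path(directory)
        meta = json.loads((d / "channels.json").read_text())
        return cls(
            data=np.load(d / "epochs.npy"),
            sfreq=meta["sfreq"],
            tmin_ms=meta["tmin_ms"],
            channels=list(meta["channels"]),
            metadata=pd.read_csv(d / "trials.csv"),
        )

    @classmethod
    def from_edf(cls, path, onsets_s, metadata, tmin_ms=-200.0, tmax_ms=2000.0,
                 channels=None) -> "EpochSet":
        """Epoch a continuous EDF recording around given onset times.

        Requires :mod:`mne`.  ``onsets_s`` are event times in seconds;
        ``metadata`` must have one row per onset.
        """
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        if channels is not None:
            raw.pick(channels)
        sfreq = float(raw.info["sfreq"])
        sig = raw.get_data() * 1e6  # volts -> microvolts
        n_samp = int(round((tmax_ms - tmin_ms) * sfreq / 1000.0))
        offset = int(round(tmin_ms * sfreq / 1000.0))
        epochs = []
        for t in onsets_s:
            i0 = int(round(t * sfreq)) + offset
            if i0 < 0 or i0 + n_samp > sig.shape[1]:
                raise ValueError(f"epoch around onset {t} s falls outside the recording")
            epochs.append(sig[:, i0 : i0 + n_samp])
        return cls(
            data=np.stack(epochs),
            sfreq=sfreq,
            tmin_ms=tmin_ms,
            channels=list(raw.ch_names),
            metadata=pd.DataFrame(metadata),
        )

    def require_cda_channels(self) -> None:
        self.channel_index(CDA_CHANNELS)
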