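"""Synthetic lateralized ERP epochs with a set-size-dependent CDA.

The generator emulates the statistical structure the CDA pipeline assumes:
500-Hz epochs from -200 to 2000 ms around memory-array onset, a
contralateral negativity on the four posterior electrode pairs whose
amplitude follows ``a * min(N, K_plateau)`` plus an optional additive
stimulus-type offset, 1/f-shapeable Gaussian noise, and injectable
artifacts (blink, saccade, drift, muscle, step, flatline) whose amplitudes
exceed their detection thresholds by construction (1.5x by default) and
which are labeled per class and trial in the metadata.

Two study-level regimes follow from ``k_plateau``:

* equal plateaus + a type offset -> the contra-ipsi difference between
  stimulus types is constant across set sizes (additive pattern);
* distinct plateaus per type -> the difference grows with set size
  (capacity-expansion pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from wmcda._utils import CDA_PAIRS
from wmcda.cda.epochs import EpochSet

__all__ = ["ERPSimSpec", "gen_erp_epochs", "ARTIFACT_CLASSES"]

ARTIFACT_CLASSES = ("blink", "saccade", "drift", "muscle", "step", "flatline")

#: 10-20 scalp sites recordable in this montage, plus ocular/gaze channels.
VALID_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "F4", "F8", "Fz", "FC5", "FC6", "FC1", "FC2",
    "C3", "C4", "Cz", "CP5", "CP6", "CP1", "CP2", "P7", "P8", "P3", "P4",
    "Pz", "PO7", "PO8", "PO3", "PO4", "O1", "O2", "Oz",
    "VEOG", "HEOG", "GAZE_X", "GAZE_Y",
)

_LEFT = tuple(p[0] for p in CDA_PAIRS)
_RIGHT = tuple(p[1] for p in CDA_PAIRS)

#: Injection amplitudes default to 1.5x the corresponding detection
#: threshold (blink vs the 50 uV EOG absolute test, saccade vs the 30 uV
#: EOG step test, drift vs 75 uV fitted change, muscle vs 75 uV
#: peak-to-peak, step vs 60 uV).
DEFAULT_ARTIFACT_AMPLITUDES = {
    "blink": 75.0,
    "saccade": 45.0,
    "drift": 112.5,
    "muscle": 112.5,
    "step": 90.0,
}


@dataclass(frozen=True)
class ERPSimSpec:
    """Generative conditions for the lateralized EEG experiment.

    Defaults mirror the study's recording and design parameters: 500 Hz,
    -200..2000 ms epochs, set sizes 1/3/5 for repeated colors vs
    trial-unique objects, 18 participants with 200 trials per cell, CDA
    slope -0.8 uV/item saturating at K_plateau = 3 items, an additive
    -0.5 uV offset for objects, and 10 uV-RMS pink (1/f) noise.
    """

    sfreq: float = 500.0
    tmin_ms: float = -200.0
    tmax_ms: float = 2000.0
    set_sizes: tuple[int, ...] = (1, 3, 5)
    stim_types: tuple[str, ...] = ("CLR_REP", "OBJ_UNI")
    amp_per_item: float = -0.8           # uV per stored item
    k_plateau: float | Mapping[str, float] = 3.0
    type_offset: Mapping[str, float] = field(
        default_factory=lambda: {"CLR_REP": 0.0, "OBJ_UNI": -0.5}
    )
    onset_ms: float = 200.0              # CDA ramp start
    full_ms: float = 400.0               # CDA at full amplitude from here on
    #: common evoked response on all eight posterior channels (uV); the
    #: lateralized CDA increment rides on top of this bilateral activity,
    #: and it cancels exactly in the contra-ipsi difference.
    bilateral_amp: float = -1.0
    noise_rms: float = 10.0              # uV
    #: spectral exponent beta of the 1/f^beta noise power; EEG background
    #: activity is dominated by low frequencies, so pink (beta = 1) is the
    #: default; 0 gives white noise.
    noise_exponent: float = 1.0
    artifact_rates: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in ARTIFACT_CLASSES}
    )
    artifact_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARTIFACT_AMPLITUDES)
    )
    channels: tuple[str, ...] = (*_LEFT, *_RIGHT, "VEOG", "HEOG")
    include_gaze: bool = False
    gaze_noise_deg: float = 0.05
    n_participants: int = 18
    n_trials_per_cell: int = 200
    seed: int = 0

    def __post_init__(self):
        unknown = [ch for ch in self.channels if ch not in VALID_CHANNELS]
        if unknown:
            raise ValueError(
                f"unknown channel name(s) {unknown}; valid names: {list(VALID_CHANNELS)}"
            )
        for cls_, rate in self.artifact_rates.items():
            if cls_ not in ARTIFACT_CLASSES:
                raise ValueError(f"unknown artifact class {cls_!r}; valid: {ARTIFACT_CLASSES}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"artifact rate for {cls_!r} must be in [0, 1]")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")
        plateaus = (
            self.k_plateau.values() if isinstance(self.k_plateau, Mapping) else [self.k_plateau]
        )
        if any(k <= 0 for k in plateaus):
            raise ValueError("k_plateau must be positive")

    @property
    def all_channels(self) -> tuple[str, ...]:
        if self.include_gaze:
            return (*self.channels, "GAZE_X", "GAZE_Y")
        return self.channels

    @property
    def n_samples(self) -> int:
        return int(round((self.tmax_ms - self.tmin_ms) * self.sfreq / 1000.0))

    def plateau_of(self, stim_type: str) -> float:
        if isinstance(self.k_plateau, Mapping):
            return float(self.k_plateau[stim_type])
        return float(self.k_plateau)

    def cda_amplitude(self, stim_type: str, set_size: int) -> float:
        """Expected contra-ipsi amplitude (uV) in the analysis window."""
        amp = self.amp_per_item * min(set_size, self.plateau_of(stim_type))
        return amp + float(self.type_offset.get(stim_type, 0.0))


def _cda_waveform(spec: ERPSimSpec) -> np.ndarray:
    """Unit waveform: 0 before onset, linear ramp, 1 from full_ms onward."""
    t = spec.tmin_ms + np.arange(spec.n_samples) * 1000.0 / spec.sfreq
    w = np.clip((t - spec.onset_ms) / (spec.full_ms - spec.onset_ms), 0.0, 1.0)
    return w


def _shaped_noise(rng, shape, rms, exponent, sfreq):
    """Gaussian noise, optionally spectrally shaped to 1/f^exponent power."""
    if rms == 0.0:
        return np.zeros(shape, dtype=np.float32)
    white = rng.standard_normal(shape)
    if exponent == 0.0:
        return (rms * white).astype(np.float32)
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC power
    spectrum = np.fft.rfft(white, axis=-1) * scale
    shaped = np.fft.irfft(spectrum, n=n, axis=-1)
    shaped *= rms / np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    return shaped.astype(np.float32)


def gen_erp_epochs(spec: ERPSimSpec) -> EpochSet:
    """Simulate an :class:`~wmcda.cda.epochs.EpochSet` with ground-truth labels.

    The metadata carries ``cue_side`` (balanced within each cell),
    ``set_size``, ``stim_type``, ``participant``, one boolean ``art_<class>``
    column per artifact class and their union ``art_any``.
    """
    rng = np.random.default_rng(spec.seed)
    channels = list(spec.all_channels)
    n_samp = spec.n_samples
    ch_idx = {ch: i for i, ch in enumerate(channels)}
    eeg_idx = [ch_idx[ch] for ch in channels if ch not in ("VEOG", "HEOG", "GAZE_X", "GAZE_Y")]
    wave = _cda_waveform(spec)
    amps = spec.artifact_amplitudes
    fs = spec.sfreq

    data_parts, meta_parts = [], []
    for part in range(spec.n_participants):
        cells = [
            (stim, n) for stim in spec.stim_types for n in spec.set_sizes
        ]
        n_cell = spec.n_trials_per_cell
        n_trials = len(cells) * n_cell
        block = _shaped_noise(
            rng, (n_trials, len(channels), n_samp), spec.noise_rms,
            spec.noise_exponent, fs,
        )
        if spec.include_gaze:
            gx, gy = ch_idx["GAZE_X"], ch_idx["GAZE_Y"]
            block[:, [gx, gy], :] = spec.gaze_noise_deg * rng.standard_normal(
                (n_trials, 2, n_samp)
            ).astype(np.float32)

        meta = pd.DataFrame(
            {
                "participant": part,
                "stim_type": np.repeat([c[0] for c in cells], n_cell),
                "set_size": np.repeat([c[1] for c in cells], n_cell),
            }
        )
        # balanced cue sides within each cell
        half = n_cell // 2
        side_cell = np.array(["left"] * half + ["right"] * (n_cell - half))
        sides = np.concatenate([rng.permutation(side_cell) for _ in cells])
        meta["cue_side"] = sides

        # CDA: contralateral channels get the amplitude-scaled waveform
        left_idx = [ch_idx[ch] for ch in _LEFT]
        right_idx = [ch_idx[ch] for ch in _RIGHT]
        amp_arr = np.array(
            [
                spec.cda_amplitude(s, int(n))
                for s, n in zip(meta["stim_type"], meta["set_size"])
            ],
            dtype=np.float32,
        )
        wave32 = wave.astype(np.float32)
        if spec.bilateral_amp != 0.0:
            block[:, left_idx + right_idx, :] += np.float32(spec.bilateral_amp) * wave32
        for side, contra in (("left", right_idx), ("right", left_idx)):
            m = np.flatnonzero(sides == side)
            block[np.ix_(m, contra)] += amp_arr[m][:, None, None] * wave32

        # artifact injection
        labels = {c: np.zeros(n_trials, dtype=bool) for c in ARTIFACT_CLASSES}
        for t_i in range(n_trials):
            for cls_ in ARTIFACT_CLASSES:
                rate = float(spec.artifact_rates.get(cls_, 0.0))
                if rate <= 0.0 or rng.random() >= rate:
                    continue
                labels[cls_][t_i] = True
                if cls_ == "blink":
                    # 400-ms biphasic deflection on VEOG
                    width = int(round(0.400 * fs))
                    start = rng.integers(0, n_samp - width + 1)
                    shape = np.sin(2 * np.pi * np.arange(width) / width)
                    block[t_i, ch_idx["VEOG"], start : start + width] += (
                        amps["blink"] * shape
                    ).astype(np.float32)
                elif cls_ == "saccade":
                    onset = rng.integers(n_samp // 10, n_samp - n_samp // 10)
                    sign = rng.choice([-1.0, 1.0])
                    block[t_i, ch_idx["HEOG"], onset:] += np.float32(sign * amps["saccade"])
                    if spec.include_gaze:
                        block[t_i, ch_idx["GAZE_X"], onset:] += np.float32(sign * 1.0)
                elif cls_ == "drift":
                    ch = rng.choice(eeg_idx)
                    ramp = np.linspace(0.0, rng.choice([-1.0, 1.0]) * amps["drift"], n_samp)
                    block[t_i, ch, :] += ramp.astype(np.float32)
                elif cls_ == "muscle":
                    # band-limited high-frequency burst
                    width = int(round(0.300 * fs))
                    start = rng.integers(0, n_samp - width + 1)
                    tt = np.arange(width) / fs
                    burst = (amps["muscle"] / 2.0) * np.sin(
                        2 * np.pi * rng.uniform(40.0, 70.0) * tt
                    )
                    ch = rng.choice(eeg_idx)
                    block[t_i, ch, start : start + width] += burst.astype(np.float32)
                elif cls_ == "step":
                    onset = rng.integers(n_samp // 10, n_samp - n_samp // 10)
                    ch = rng.choice(eeg_idx)
                    block[t_i, ch, onset:] += np.float32(
                        rng.choice([-1.0, 1.0]) * amps["step"]
                    )
                elif cls_ == "flatline":
                    ch = rng.choice(eeg_idx)
                    block[t_i, ch, :] = 0.0
        for cls_ in ARTIFACT_CLASSES:
            meta[f"art_{cls_}"] = labels[cls_]
        meta["art_any"] = np.logical_or.reduce([labels[c] for c in ARTIFACT_CLASSES])

        data_parts.append(block)
        meta_parts.append(meta)

    return EpochSet(
        data=np.concatenate(data_parts),
        sfreq=fs,
        tmin_ms=spec.tmin_ms,
        channels=channels,
        metadata=pd.concat(meta_parts, ignore_index=True),
    )
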