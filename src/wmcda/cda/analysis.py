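"""CDA computation and the set-size x stimulus-type additivity test.

The contralateral delay activity (CDA) is the mean amplitude difference
between the posterior electrodes contralateral and ipsilateral to the
cued hemifield, averaged over the four pairs P3/P4, P7/P8, PO3/PO4,
PO7/PO8 and over the samples of a measurement window.  Three windows are
analyzed: encoding (400-1000 ms), delay (1400-2000 ms) and the combined
window (400-2000 ms).  Epochs are baseline-corrected to the -200..0 ms
pre-stimulus mean before measurement.

If a stimulus type truly increases the number of stored items, the CDA
set-size function should diverge across types (a set-size x type
interaction); a purely stimulus-driven effect predicts a constant
(additive) offset.  :func:`test_additivity` runs the two-way
repeated-measures ANOVA and renders that verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wmcda._utils import CDA_PAIRS
from wmcda.behavior import rm_anova
from wmcda.cda.epochs import EpochSet

__all__ = ["DEFAULT_WINDOWS", "CDAResult", "compute_cda", "AdditivityResult", "test_additivity"]

DEFAULT_WINDOWS = {
    "encoding": (400.0, 1000.0),
    "delay": (1400.0, 2000.0),
    "combined": (400.0, 2000.0),
}


@dataclass
class CDAResult:
    """Windowed contra-ipsi amplitudes per participant and design cell.

    ``per_participant`` is long-format with one row per participant x
    stim_type x set_size and one column per window; ``grand`` aggregates
    mean and SEM across participants.
    """

    per_participant: pd.DataFrame
    grand: pd.DataFrame
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))

    def cell_means(self, window: str = "combined") -> pd.DataFrame:
        """Participant x type x set-size means of one window (ANOVA input)."""
        return self.per_participant[["participant", "stim_type", "set_size", window]].rename(
            columns={window: "amplitude"}
        )


def compute_cda(
    epochs: EpochSet,
    windows: dict | None = None,
    baseline_ms: tuple[float, float] | None = (-200.0, 0.0),
) -> CDAResult:
    """Compute windowed CDA amplitudes from epoched data.

    Parameters
    ----------
    epochs : EpochSet
        Must contain all eight CDA electrodes and metadata columns
        ``participant``, ``cue_side``, ``stim_type``, ``set_size``.
    windows : mapping name -> (start_ms, end_ms), default the
        encoding/delay/combined windows.
    baseline_ms : interval averaged per channel per epoch and subtracted;
        ``None`` disables baseline correction.

    Notes
    -----
    Window means use the half-open sample convention, so the combined
    window equals the time-weighted mean of its samples and, at equal
    window lengths, the average of the encoding and delay windows is not
    in general equal to the combined window (the 1000-1400 ms samples
    belong only to the latter).
    """
    windows = dict(DEFAULT_WINDOWS) if windows is None else dict(windows)
    epochs.require_cda_channels()
    meta = epochs.metadata
    for col in ("participant", "cue_side", "stim_type", "set_size"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    left_idx = epochs.channel_index([p[0] for p in CDA_PAIRS])
    right_idx = epochs.channel_index([p[1] for p in CDA_PAIRS])

    data = epochs.data.astype(float)
    if baseline_ms is not None:
        b0, b1 = epochs.sample_window(*baseline_ms)
        data = data - data[:, :, b0:b1].mean(axis=2, keepdims=True)

    left = data[:, left_idx, :].mean(axis=1)
    right = data[:, right_idx, :].mean(axis=1)
    cue = meta["cue_side"].to_numpy()
    if not set(np.unique(cue)) <= {"left", "right"}:
        raise ValueError("cue_side must be 'left' or 'right'")
    contra = np.where((cue == "left")[:, None], right, left)
    ipsi = np.where((cue == "left")[:, None], left, right)
    diff = contra - ipsi  # (trials, samples)

    cols = {}
    for name, (w0, w1) in windows.items():
        i0, i1 = epochs.sample_window(w0, w1)
        cols[name] = diff[:, i0:i1].mean(axis=1)
    trial_df = pd.concat(
        [meta[["participant", "stim_type", "set_size"]].reset_index(drop=True),
         pd.DataFrame(cols)], axis=1,
    )
    per_part = (
        trial_df.groupby(["participant", "stim_type", "set_size"], sort=True)
        .mean()
        .reset_index()
    )
    grand = (
        per_part.groupby(["stim_type", "set_size"], sort=True)[list(windows)]
        .agg(["mean", "sem"])
        .reset_index()
    )
    return CDAResult(per_participant=per_part, grand=grand, windows=windows)


@dataclass
class AdditivityResult:
    """Two-way RM-ANOVA on CDA cell means plus the additivity verdict."""

    anova: pd.DataFrame
    verdict: str                      # 'additive', 'interactive', 'indeterminate'
    window: str
    alpha: float

    def effect(self, name: str) -> pd.Series:
        row = self.anova[self.anova["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def test_additivity(
    result: CDAResult,
    window: str = "combined",
    alpha: float = 0.05,
) -> AdditivityResult:
    """Test whether the stimulus-type CDA effect is additive across set sizes.

    Runs the stimulus-type x set-size repeated-measures ANOVA on the
    participant cell means of one window.  Verdict:

    * ``interactive`` — the interaction is significant at ``alpha``
      (the capacity-expansion signature);
    * ``additive`` — the interaction is not significant but the
      stimulus-type main effect is (a constant offset);
    * ``indeterminate`` — neither.
    """
    cells = result.cell_means(window)
    if cells["stim_type"].nunique() < 2 or cells["set_size"].nunique() < 2:
        raise ValueError("need >= 2 stimulus types and >= 2 set sizes")
    anova = rm_anova(cells, dv="amplitude", within=["stim_type", "set_size"],
                     subject="participant")
    p_type = float(anova.loc[anova["effect"] == "stim_type", "p"].iloc[0])
    p_inter = float(anova.loc[anova["effect"] == "stim_type * set_size", "p"].iloc[0])
    if p_inter < alpha:
        verdict = "interactive"
    elif p_type < alpha:
        verdict = "additive"
    else:
        verdict = "indeterminate"
    return AdditivityResult(anova=anova, verdict=verdict, window=window, alpha=alpha)
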