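"""Model-fit overlays: predicted ROC curves over empirical operating points."""

from __future__ import annotations

import numpy as np
import pandas as pd

from wmcda.dpsd.likelihood import DPSDParams, dpsd_predict

__all__ = ["fit_curves", "plot_fit"]


def fit_curves(results, trials: pd.DataFrame | None = None, grid: int = 101) -> dict:
    """Plot-ready predicted and observed ROC series per participant.

    Parameters
    ----------
    results : DPSDResults
    trials : DataFrame, optional
        Binned trial table; when given, empirical ROC points are attached.
    grid : int
        Number of criterion values for the smooth predicted curve.

    Returns
    -------
    dict
        ``{participant: {condition: {"far_pred", "hr_pred", "far_obs",
        "hr_obs"}}}`` — predicted curves from posterior-mean
        participant-level parameters; observed cumulative points from the
        data.
    """
    from wmcda.behavior import build_roc

    params = results.participant_params()
    crit = results.participant_criteria()
    part_index = {p: i for i, p in enumerate(results.model.participants)}
    c_grid = np.linspace(-3.0, 4.0, grid)

    rocs = {}
    if trials is not None:
        rocs = build_roc(trials)

    from scipy.special import ndtr

    out: dict = {}
    for _, row in params.iterrows():
        pid, cond = row["participant"], row["condition"]
        R, F = row["R"], row["F"]
        entry = {
            "far_pred": 1.0 - ndtr(c_grid),
            "hr_pred": R + (1.0 - R) * ndtr(F - c_grid),
            "far_pred_points": None,
            "hr_pred_points": None,
            "far_obs": None,
            "hr_obs": None,
        }
        ci = crit[part_index[pid]]
        far_pts, hr_pts = dpsd_predict(DPSDParams(R, F, tuple(ci)))
        entry["far_pred_points"], entry["hr_pred_points"] = far_pts, hr_pts
        if (pid, cond) in rocs:
            curve = rocs[(pid, cond)]
            entry["far_obs"], entry["hr_obs"] = curve.far, curve.hr
        out.setdefault(pid, {})[cond] = entry
    return out


def plot_fit(results, trials=None, participants=None, ax=None):
    """Render per-participant predicted-vs-observed ROC overlays.

    Returns the matplotlib figure; the underlying series come from
    :func:`fit_curves` and can be used without rendering.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    curves = fit_curves(results, trials)
    if participants is None:
        participants = list(curves)
    missing = [p for p in participants if p not in curves]
    if missing:
        raise ValueError(f"participants absent from fit: {missing}")
    n = len(participants)
    ncol = min(4, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow), squeeze=False)
    for ax_, pid in zip(axes.ravel(), participants):
        for cond, entry in curves[pid].items():
            (line,) = ax_.plot(entry["far_pred"], entry["hr_pred"], lw=1, label=str(cond))
            if entry["far_obs"] is not None:
                ax_.plot(entry["far_obs"], entry["hr_obs"], "o", ms=3, color=line.get_color())
        ax_.plot([0, 1], [0, 1], ":", color="grey", lw=0.5)
        ax_.set_title(str(pid), fontsize=8)
        ax_.set_xlim(0, 1)
        ax_.set_ylim(0, 1)
    for ax_ in axes.ravel()[n:]:
        ax_.set_visible(False)
    fig.tight_layout()
    return fig
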