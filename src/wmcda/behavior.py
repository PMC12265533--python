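"""Behavioral analyses: confidence binning, hit/false-alarm rates, Cowan's K,
ROC construction, and repeated-measures statistics.

Capacity is estimated with the single-probe change-detection formula
``K = N * (H - FA)`` where ``N`` is the set size, ``H`` the hit rate and
``FA`` the false-alarm rate.  Confidence responses on the semicircular
rating dial are binned into six ordinal levels (1 = surely-new ...
6 = surely-old); an "old" response is any bin >= 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from wmcda._utils import N_BINS

__all__ = [
    "RejectedResponseError",
    "DegenerateTestError",
    "bin_confidence",
    "compute_rates",
    "ROCCurve",
    "build_roc",
    "roc_from_counts",
    "rm_anova",
    "pairwise_tests",
]


class RejectedResponseError(ValueError):
    """A response angle fell in one of the dial's 90-degree gap regions."""


class DegenerateTestError(ValueError):
    """A paired test with zero variance of differences and nonzero mean."""


# --------------------------------------------------------------------------- #
# confidence binning
#
# The response dial is a semicircular scale split into a right "OLD" arc and
# a left "NEW" arc, each 90 degrees wide, separated by 90-degree gaps at the
# top and bottom of the circle.  Angles are in degrees, measured
# counterclockwise from the 3-o'clock direction.  The continuous scale runs
# from surely-new at the bottom-left end (225 deg), up the left arc to
# guess-new at the top-left (135 deg), across the top gap to guess-old at the
# top-right (45 deg), and down the right arc to surely-old at the
# bottom-right (-45 deg).  Each arc is divided into three 30-degree bins; a
# boundary angle is assigned to the lower-numbered bin.

def bin_confidence(angle: float) -> int:
    """Map a dial angle (degrees) to a confidence bin 1..6.

    Raises :class:`RejectedResponseError` for angles in the gap regions.
    """
    a = float(angle) % 360.0
    if a >= 315.0:
        a -= 360.0  # old side, lower quarter -> [-45, 0)
    if -45.0 <= a <= 45.0:  # OLD arc: bins 4 (top) .. 6 (bottom)
        if a >= 15.0:
            return 4
        if a >= -15.0:
            return 5
        return 6
    if 135.0 <= a <= 225.0:  # NEW arc: bins 3 (top) .. 1 (bottom)
        if a >= 195.0:
            return 1
        if a >= 165.0:
            return 2
        return 3
    raise RejectedResponseError(f"angle {angle!r} deg lies in a gap region of the dial")


# --------------------------------------------------------------------------- #
# rates and Cowan's K

def _old_response_column(trials: pd.DataFrame) -> pd.Series:
    if "old_response" in trials.columns:
        return trials["old_response"].astype(bool)
    if "response" in trials.columns:
        resp = trials["response"]
        if not np.issubdtype(np.asarray(resp).dtype, np.number):
            raise ValueError("'response' must be numeric confidence bins; "
                             "provide a boolean 'old_response' column otherwise")
        return resp >= (N_BINS // 2 + 1)  # bins 4..6
    raise ValueError("trials need a 'response' or 'old_response' column")


def compute_rates(trials: pd.DataFrame, set_size: int | None = None) -> pd.DataFrame:
    """Hit rate, false-alarm rate and Cowan's K per design cell.

    Parameters
    ----------
    trials : DataFrame
        Columns ``participant``, ``probe_status`` ('old'/'new'), either
        ``response`` (confidence bin, old = bins 4-6) or boolean
        ``old_response``, plus optional ``condition``/``stim_type`` and
        ``set_size`` grouping columns.
    set_size : int, optional
        Set size ``N`` for the K formula when the table has no
        ``set_size`` column.

    Returns
    -------
    DataFrame with one row per participant x condition (x set size) and
    columns ``hit_rate``, ``fa_rate``, ``K``.  Rates are computed with
    exact rational arithmetic on the counts before conversion to float;
    ``K = N * (H - FA)`` holds exactly.  K may be negative (below-chance
    cells are retained).
    """
    df = trials.copy()
    if not set(df["probe_status"].unique()) <= {"old", "new"}:
        raise ValueError("probe_status must be 'old' or 'new'")
    df["_old_resp"] = _old_response_column(df)
    group_cols = ["participant"]
    for col in ("condition", "stim_type"):
        if col in df.columns:
            group_cols.append(col)
    if "set_size" in df.columns:
        group_cols.append("set_size")
    elif set_size is None:
        raise ValueError("provide a set_size argument or a set_size column")

    rows = []
    for key, cell in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n_old = int((cell["probe_status"] == "old").sum())
        n_new = int((cell["probe_status"] == "new").sum())
        if n_old == 0 or n_new == 0:
            raise ValueError(f"cell {dict(zip(group_cols, key))} lacks old or new trials")
        hits = int(cell.loc[cell["probe_status"] == "old", "_old_resp"].sum())
        fas = int(cell.loc[cell["probe_status"] == "new", "_old_resp"].sum())
        h = Fraction(hits, n_old)
        fa = Fraction(fas, n_new)
        n_items = int(key[group_cols.index("set_size")]) if "set_size" in group_cols else int(set_size)
        k = n_items * (h - fa)
        row = dict(zip(group_cols, key))
        row.update(hit_rate=float(h), fa_rate=float(fa), K=float(k),
                   n_old=n_old, n_new=n_new, set_size=n_items)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# ROC construction

@dataclass(frozen=True)
class ROCCurve:
    """Cumulative ROC for one participant x condition.

    ``far``/``hr`` hold the five interior operating points ordered from the
    strictest criterion (bin-6 responses only) to the most lenient (bins
    2-6); the implicit endpoints (0, 0) and (1, 1) are not stored.
    ``counts`` is the underlying 2x6 table (row 0 old, row 1 new, bins
    1..6).
    """

    far: np.ndarray
    hr: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.far) < 0) or np.any(np.diff(self.hr) < 0):
            raise ValueError("cumulative ROC points must be non-decreasing")


def roc_from_counts(old_counts, new_counts) -> ROCCurve:
    """Build the cumulative ROC from 6-bin response counts (bins 1..6)."""
    old = np.asarray(old_counts, dtype=np.int64)
    new = np.asarray(new_counts, dtype=np.int64)
    if old.shape != (N_BINS,) or new.shape != (N_BINS,):
        raise ValueError(f"expected {N_BINS} bins per class")
    if old.sum() == 0 or new.sum() == 0:
        raise ValueError("need at least one old and one new trial")
    hr = np.cumsum(old[::-1])[:-1] / old.sum()
    far = np.cumsum(new[::-1])[:-1] / new.sum()
    return ROCCurve(far=far, hr=hr, counts=np.stack([old, new]))


def build_roc(trials: pd.DataFrame) -> dict[tuple, ROCCurve]:
    """Cumulative ROC per participant x condition from binned trials.

    Returns a dict keyed by ``(participant, condition)``.
    """
    out = {}
    cond_col = "condition" if "condition" in trials.columns else None
    group_cols = ["participant"] + ([cond_col] if cond_col else [])
    for key, cell in trials.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key, None)
        resp = cell["response"].to_numpy()
        old = np.bincount(resp[cell["probe_status"] == "old"] - 1, minlength=N_BINS)
        new = np.bincount(resp[cell["probe_status"] == "new"] - 1, minlength=N_BINS)
        out[tuple(key)] = roc_from_counts(old, new)
    return out


# --------------------------------------------------------------------------- #
# repeated-measures statistics

def _safe_rm_frame(data, dv, within, subject):
    """Rename columns to dodge a dv/level name clash inside pingouin."""
    within = [within] if isinstance(within, str) else list(within)
    mapping = {dv: "_dv_", subject: "_subj_"}
    mapping.update({w: f"_w{i}_" for i, w in enumerate(within)})
    df = data[[subject, *within, dv]].rename(columns=mapping)
    return df, "_dv_", [f"_w{i}_" for i in range(len(within))], "_subj_"


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str) -> pd.DataFrame:
    """One- or two-way repeated-measures ANOVA (no sphericity correction).

    Parameters
    ----------
    data : long-format DataFrame of cell means (one row per subject x cell).
    dv, subject : column names.
    within : str or list of 1-2 within-subject factor columns.

    Returns
    -------
    DataFrame with one row per effect and columns ``effect``, ``F``,
    ``df1``, ``df2``, ``p``, ``np2`` (partial eta squared).  Uncorrected
    p-values with integer degrees of freedom are reported.

    Raises on incomplete/unbalanced designs or fewer than 2 subjects.
    """
    import pingouin as pg

    within_list = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within_list) <= 2:
        raise ValueError("within must name 1 or 2 factors")
    cells = data.groupby([subject, *within_list], sort=False).size()
    if cells.max() > 1:
        raise ValueError("expected one row per subject x cell (cell means)")
    n_subj = data[subject].nunique()
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    expected = n_subj * int(np.prod([data[w].nunique() for w in within_list]))
    if len(data) != expected:
        raise ValueError("incomplete design: missing cells")

    df, dv_, within_, subj_ = _safe_rm_frame(data, dv, within_list, subject)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.rm_anova(data=df, dv=dv_, within=within_ if len(within_) > 1 else within_[0],
                          subject=subj_, detailed=True, effsize="np2")
    res = res[res["Source"] != "Error"].copy()
    # a zero-SS effect with zero error SS is reported as F = 0 (no effect)
    for col, default in (("F", np.nan), ("p_unc", np.nan), ("np2", np.nan)):
        if col not in res.columns:
            res[col] = default
    degenerate = res["F"].isna() & (res["SS"] == 0)
    res.loc[degenerate, ["F", "p_unc", "np2"]] = [0.0, 1.0, 0.0]
    name_map = {w_: w for w_, w in zip(within_, within_list)}
    if len(within_list) == 2:
        name_map[f"{within_[0]} * {within_[1]}"] = f"{within_list[0]} * {within_list[1]}"
        df1 = res["ddof1"].to_numpy()
        df2 = res["ddof2"].to_numpy()
        p = res["p_unc"].to_numpy()
    else:
        df1 = res["DF"].to_numpy()
        err_df = (n_subj - 1) * df1
        df2 = err_df
        p = res["p_unc"].to_numpy()
    out = pd.DataFrame({
        "effect": [name_map.get(s, s) for s in res["Source"]],
        "F": res["F"].to_numpy(),
        "df1": df1.astype(int),
        "df2": np.asarray(df2).astype(int),
        "p": p,
        "np2": res["np2"].to_numpy(),
    })
    return out


def pairwise_tests(data: pd.DataFrame, dv: str, within: str, subject: str,
                   correction: str = "bonferroni") -> pd.DataFrame:
    """Paired t-tests between all level pairs of one within-subject factor.

    Bonferroni correction multiplies each p by the number of pairs, capped
    at 1.  Cohen's d uses the SD of the difference scores (equivalently
    ``d = t / sqrt(n)``).

    A pair whose difference scores have zero variance yields ``t = 0``,
    ``p = 1``, ``d = 0`` when the mean difference is also zero, and raises
    :class:`DegenerateTestError` otherwise.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("incomplete design: missing cells")
    if len(wide) < 2:
        raise ValueError("need at least 2 subjects")
    levels = list(wide.columns)
    pairs = list(combinations(levels, 2))
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        diff = (wide[a] - wide[b]).to_numpy(dtype=float)
        n = diff.size
        sd = diff.std(ddof=1)
        if sd == 0.0:
            if diff.mean() != 0.0:
                raise DegenerateTestError(f"zero variance of differences for pair ({a}, {b})")
            t, p, d = 0.0, 1.0, 0.0
        else:
            t, p = stats.ttest_rel(wide[a], wide[b])
            d = float(diff.mean() / sd)
        p_corr = min(1.0, p * n_pairs) if correction == "bonferroni" else p
        rows.append({"A": a, "B": b, "t": float(t), "df": n - 1,
                     "p_unc": float(p), "p_corr": float(p_corr), "cohen_d": d})
    return pd.DataFrame(rows)
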