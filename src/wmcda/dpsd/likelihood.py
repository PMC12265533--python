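"""Dual-process signal-detection (DPSD) model: parameters, ROC, likelihood.

The DPSD model assumes recognition judgments arise from two independent
processes: *recollection*, an all-or-none retrieval of contextual detail
that occurs with probability ``R`` for studied (old) probes, and
*familiarity*, a continuous equal-variance signal-detection process in
which old probes draw memory strength from ``N(F, 1)`` and new probes from
``N(0, 1)``.  Confidence responses are produced by comparing strength to
five ordered criteria ``c1 < ... < c5``, yielding six ordinal bins
(1 = surely-new ... 6 = surely-old).  Recollected old probes always
produce the highest-confidence old response (bin 6); recollection never
occurs for new probes.

The model ROC at criterion ``c`` is::

    HR(c)  = R + (1 - R) * Phi(F - c)
    FAR(c) = 1 - Phi(c)

so the predicted ROC has a y-intercept of ``R`` and curvilinearity
governed by ``F``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ndtr

from wmcda._utils import N_BINS, check_increasing, check_probability

__all__ = ["DPSDParams", "dpsd_predict", "bin_probabilities", "dpsd_loglik"]


@dataclass(frozen=True)
class DPSDParams:
    """One condition's generative DPSD parameters.

    Parameters
    ----------
    recollection : float
        Probability of all-or-none recollection for old probes, in [0, 1].
    familiarity : float
        Mean strength of the old-item familiarity distribution, in
        standard-normal-distance units (the model's d').
    criteria : sequence of 5 floats
        Strictly increasing response criteria on the familiarity axis.
    """

    recollection: float
    familiarity: float
    criteria: tuple[float, ...] = field(default=(-0.6, 0.0, 0.85, 1.4, 2.0))

    def __post_init__(self):
        check_probability(self.recollection, "recollection")
        crit = check_increasing(self.criteria, "criteria")
        if crit.size != N_BINS - 1:
            raise ValueError(f"criteria must have {N_BINS - 1} values, got {crit.size}")
        object.__setattr__(self, "criteria", tuple(float(c) for c in crit))


def dpsd_predict(params: DPSDParams) -> tuple[np.ndarray, np.ndarray]:
    """Predicted cumulative (FAR, HR) operating points at each criterion.

    Returns the five ROC points ordered from the strictest criterion
    (``c5``, "surely-old" responses only) to the most lenient (``c1``),
    i.e. both returned sequences are non-decreasing, tracing the ROC from
    near (0, 0) toward (1, 1).
    """
    c = np.asarray(params.criteria, dtype=float)[::-1]
    far = 1.0 - ndtr(c)
    hr = params.recollection + (1.0 - params.recollection) * ndtr(params.familiarity - c)
    return far, hr


def bin_probabilities(params: DPSDParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin response probabilities ``(p_old, p_new)``, bins 1..6.

    Bin probabilities are successive differences of the cumulative response
    functions; each vector sums to 1 exactly (up to float rounding).
    """
    c = np.asarray(params.criteria, dtype=float)
    new_edges = np.concatenate(([0.0], ndtr(c), [1.0]))
    p_new = np.diff(new_edges)
    old_edges = np.concatenate(([0.0], ndtr(c - params.familiarity), [1.0]))
    p_old = (1.0 - params.recollection) * np.diff(old_edges)
    p_old[-1] += params.recollection
    return p_old, p_new


def dpsd_loglik(params: DPSDParams, counts: np.ndarray) -> float:
    """Multinomial log-likelihood of a 2x6 response-count table.

    Parameters
    ----------
    params : DPSDParams
    counts : array-like, shape (2, 6)
        Row 0: old-probe response counts by bin 1..6; row 1: new-probe
        counts.  Non-negative integers.

    Returns
    -------
    float
        Sum of the old-class and new-class multinomial log-pmfs (including
        the multinomial coefficients).  Returns ``-inf`` (signaled, not
        raised) when a bin with observed counts has probability 0 under
        degenerate parameter values.
    """
    counts = np.asarray(counts)
    if counts.shape != (2, N_BINS):
        raise ValueError(f"counts must have shape (2, {N_BINS}), got {counts.shape}")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(float)
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("counts must be non-negative integers")
    counts = counts.astype(np.int64)
    p_old, p_new = bin_probabilities(params)
    total = 0.0
    for row, p in ((counts[0], p_old), (counts[1], p_new)):
        n = row.sum()
        if n == 0:
            continue
        if np.any((row > 0) & (p <= 0.0)):
            return -np.inf
        active = row > 0
        total += float(
            gammaln(n + 1)
            - gammaln(row + 1).sum()
            + (row[active] * np.log(p[active])).sum()
        )
    return total
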