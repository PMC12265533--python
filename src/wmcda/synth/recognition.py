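"""Synthetic confidence-rating recognition trials from the DPSD generative model.

Each participant x condition receives its own DPSD parameters drawn around
population means: recollection on the probit scale, familiarity on the
identity scale, and the five ordered criteria via the first-criterion +
log-increment transform, so every sampled parameter set respects the
model's constraints.  Old probes are recollected (-> bin 6, the classic
all-or-none identification) with probability R; otherwise their strength
is drawn from ``N(F, 1)`` and binned by the participant's criteria.  New
probes draw from ``N(0, 1)``; recollection never occurs for new probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wmcda._utils import CONDITIONS, N_BINS, check_increasing, check_probability

__all__ = ["DPSDPopulationSpec", "gen_recognition_trials"]


@dataclass(frozen=True)
class DPSDPopulationSpec:
    """Population-level generative conditions for the recognition experiment.

    Defaults mirror the fitted population point estimates of the study the
    generator emulates: recollection 0.35 in every condition and
    familiarity 0.93 / 0.91 / 1.10 for repeated colors, repeated objects
    and trial-unique objects; 31 participants x 120 trials per condition,
    probes old/new with equal probability.  Between-participant SDs act on
    the transformed scales.
    """

    mean_recollection: tuple[float, ...] = (0.35, 0.35, 0.35)
    mean_familiarity: tuple[float, ...] = (0.93, 0.91, 1.10)
    #: criteria span the whole rating scale, with a conservative top
    #: criterion (surely-old false alarms ~Phi(-2.9) < 1%), as in typical
    #: confidence-rating ROCs; at the old/new midpoint (c3) these means
    #: give H ~ 0.74 and FA ~ 0.20.
    criteria_means: tuple[float, ...] = (-1.2, -0.2, 0.85, 1.8, 2.9)
    sd_recollection: float = 0.08   # probit scale
    sd_familiarity: float = 0.08    # identity scale
    sd_criteria: float = 0.08       # first-criterion + log-increment scale
    conditions: tuple[str, ...] = CONDITIONS
    n_participants: int = 31
    n_trials_per_condition: int = 120
    p_old: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for r in self.mean_recollection:
            check_probability(r, "mean_recollection")
        check_increasing(self.criteria_means, "criteria_means")
        if len(self.criteria_means) != N_BINS - 1:
            raise ValueError(f"criteria_means must have {N_BINS - 1} values")
        if len(self.mean_recollection) != len(self.conditions) or len(
            self.mean_familiarity
        ) != len(self.conditions):
            raise ValueError("per-condition parameter lengths must match conditions")
        check_probability(self.p_old, "p_old")
        if self.n_participants < 1 or self.n_trials_per_condition < 2:
            raise ValueError("n_participants >= 1 and n_trials_per_condition >= 2 required")
        for name in ("sd_recollection", "sd_familiarity", "sd_criteria"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _transform_criteria(criteria: np.ndarray) -> np.ndarray:
    gamma = np.empty_like(criteria)
    gamma[0] = criteria[0]
    gamma[1:] = np.log(np.diff(criteria))
    return gamma


def _criteria_from_gamma(gamma: np.ndarray) -> np.ndarray:
    crit = np.empty_like(gamma)
    crit[..., 0] = gamma[..., 0]
    crit[..., 1:] = gamma[..., [0]] + np.cumsum(np.exp(gamma[..., 1:]), axis=-1)
    return crit


def gen_recognition_trials(spec: DPSDPopulationSpec) -> pd.DataFrame:
    """Simulate a trial table of 6-bin confidence responses.

    Returns
    -------
    DataFrame with columns ``participant``, ``condition``, ``probe_status``
    ('old'/'new'), ``response`` (bin 1..6), ``set_size``.  Within each
    participant x condition, old/new trial counts follow the even split
    implied by ``p_old`` (to within rounding).  Identical spec + seed give
    identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n_cond = len(spec.conditions)
    from scipy.special import ndtri

    rho_mu = ndtri(np.asarray(spec.mean_recollection))
    gamma_mu = _transform_criteria(np.asarray(spec.criteria_means, dtype=float))

    n_old = int(round(spec.n_trials_per_condition * spec.p_old))
    n_new = spec.n_trials_per_condition - n_old

    records = []
    for i in range(spec.n_participants):
        gamma_i = gamma_mu + rng.normal(0.0, spec.sd_criteria, gamma_mu.shape)
        crit_i = _criteria_from_gamma(gamma_i)
        for j, cond in enumerate(spec.conditions):
            from scipy.special import ndtr

            r_ij = float(ndtr(rho_mu[j] + rng.normal(0.0, spec.sd_recollection)))
            f_ij = float(spec.mean_familiarity[j] + rng.normal(0.0, spec.sd_familiarity))

            recollected = rng.random(n_old) < r_ij
            strength_old = rng.normal(f_ij, 1.0, n_old)
            bins_old = np.searchsorted(crit_i, strength_old, side="left") + 1
            bins_old[recollected] = N_BINS
            strength_new = rng.normal(0.0, 1.0, n_new)
            bins_new = np.searchsorted(crit_i, strength_new, side="left") + 1

            for status, bins in (("old", bins_old), ("new", bins_new)):
                records.append(
                    pd.DataFrame(
                        {
                            "participant": i,
                            "condition": cond,
                            "probe_status": status,
                            "response": bins.astype(np.int64),
                            "set_size": 6,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)
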