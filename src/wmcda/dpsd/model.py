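"""Hierarchical Bayesian estimation of the DPSD model.

Model
-----
For participant ``i`` and condition ``j`` the 2x6 table of confidence
responses is multinomial with DPSD bin probabilities (see
:mod:`wmcda.dpsd.likelihood`).  Participant-level parameters live on
transformed scales chosen so that every draw respects the model's
constraints:

* ``rho_ij = probit(R_ij)`` — recollection, probit link;
* ``f_ij = F_ij`` — familiarity, identity link;
* ``gamma_i = (c1, log(c2 - c1), ..., log(c5 - c4))`` — ordered criteria,
  first-criterion + log-increment link, shared across conditions within a
  participant (same response scale throughout the blocked session).

Each transformed parameter is normally distributed around a population
(fixed-effect) mean with a between-participant (random-effect) SD — the
linear predictor is the sum of the fixed and random effects, and the
variability term is the participant-by-condition interaction SD.
Priors are weakly informative: ``Normal(0, 1.5)`` on the population means
and ``HalfNormal(1)`` on the random-effect SDs (overridable).

Sampling
--------
Adaptive Metropolis-within-Gibbs: scalar random-walk Metropolis updates of
every participant-level coordinate (vectorized across participants and
conditions, proposal scales adapted toward 44% acceptance during warmup),
conjugate Gibbs draws of the population means, and random-walk Metropolis
on the log random-effect SDs.  Multiple chains run from jittered,
data-driven starting points; convergence is assessed with the split-chain
Gelman-Rubin diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from wmcda._utils import CONDITIONS, N_BINS, spawn_rngs
from wmcda.dpsd.posterior import PosteriorSummary, summarize_posterior

__all__ = [
    "DPSDPriors",
    "SamplerSettings",
    "PRESETS",
    "HierarchicalDPSD",
    "DPSDResults",
    "fit_hierarchical",
]

_N_CRIT = N_BINS - 1


@dataclass(frozen=True)
class DPSDPriors:
    """Hyperparameters of the hierarchical priors (transformed scales)."""

    mu_sd: float = 1.5          # Normal(0, mu_sd) on population means
    sigma_scale: float = 1.0    # HalfNormal(sigma_scale) on random-effect SDs


@dataclass(frozen=True)
class SamplerSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    #: inner Metropolis sweeps of the recollection/familiarity cells per
    #: iteration; R and F trade off within a cell, so extra sweeps (and a
    #: joint anti-correlated proposal) speed mixing at little cost.
    rf_sweeps: int = 3

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 10 or self.draws < 10:
            raise ValueError("need >= 1 chain and >= 10 warmup/draws")


#: ``full`` is the high-fidelity budget (12,000 post-warmup draws after
#: 12,000 warmup iterations per chain); ``test`` is the documented reduced
#: preset for continuous testing; ``acceptance`` sits in between and is
#: used by the desk-scale recovery protocols.
PRESETS = {
    "full": SamplerSettings(chains=4, warmup=12000, draws=12000),
    "acceptance": SamplerSettings(chains=4, warmup=5000, draws=5000),
    "test": SamplerSettings(chains=4, warmup=1000, draws=1000),
}

_RHAT_FLAG = 1.1  # population-level R-hat above this flags non-convergence


def _criteria_from_gamma(gamma: np.ndarray) -> np.ndarray:
    """Map (..., 5) transformed criteria to strictly increasing criteria."""
    crit = np.empty_like(gamma)
    crit[..., 0] = gamma[..., 0]
    np.cumsum(np.exp(gamma[..., 1:]), axis=-1, out=crit[..., 1:])
    crit[..., 1:] += gamma[..., [0]]
    return crit


class HierarchicalDPSD:
    """Hierarchical DPSD model of binned confidence-rating data.

    Parameters
    ----------
    counts : ndarray, shape (n_participants, n_conditions, 2, 6)
        Response counts per participant and condition; axis 2 is
        (old probes, new probes), axis 3 the confidence bins 1..6.
    participants, conditions : sequences of labels
    priors : DPSDPriors, optional
    """

    def __init__(self, counts, participants=None, conditions=None, priors=None):
        counts = np.asarray(counts)
        if counts.ndim != 4 or counts.shape[2:] != (2, N_BINS):
            raise ValueError(f"counts must be (participants, conditions, 2, {N_BINS})")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        n_p, n_c = counts.shape[:2]
        if n_p < 2 or n_c < 2:
            raise ValueError("need >= 2 participants and >= 2 conditions")
        self.participants = list(participants) if participants is not None else list(range(n_p))
        self.conditions = list(conditions) if conditions is not None else list(CONDITIONS[:n_c])
        if len(self.participants) != n_p or len(self.conditions) != n_c:
            raise ValueError("label lengths do not match counts shape")
        self.priors = priors or DPSDPriors()

    # ------------------------------------------------------------------ #
    @classmethod
    def from_dataframe(
        cls,
        trials: pd.DataFrame,
        participant_col: str = "participant",
        condition_col: str = "condition",
        probe_col: str = "probe_status",
        response_col: str = "response",
        conditions=None,
        priors=None,
    ) -> "HierarchicalDPSD":
        """Build the model from a trial-level table of binned responses."""
        for col in (participant_col, condition_col, probe_col, response_col):
            if col not in trials.columns:
                raise ValueError(f"missing column {col!r}")
        resp = trials[response_col].to_numpy()
        if np.any((resp < 1) | (resp > N_BINS)):
            raise ValueError(f"responses must be confidence bins 1..{N_BINS}")
        participants = sorted(trials[participant_col].unique())
        if conditions is None:
            conditions = sorted(trials[condition_col].unique())
        classes = ["old", "new"]
        shape = (len(participants), len(conditions), 2, N_BINS)
        counts = np.zeros(shape, dtype=np.int64)
        p_idx = trials[participant_col].map({p: i for i, p in enumerate(participants)})
        c_idx = trials[condition_col].map({c: i for i, c in enumerate(conditions)})
        s_idx = trials[probe_col].map({s: i for i, s in enumerate(classes)})
        if s_idx.isna().any():
            raise ValueError(f"{probe_col!r} must contain only {classes}")
        np.add.at(counts, (p_idx.to_numpy(), c_idx.to_numpy(), s_idx.to_numpy(), resp - 1), 1)
        return cls(counts, participants, conditions, priors)

    # ------------------------------------------------------------------ #
    # likelihood pieces, vectorized over (participant, condition)
    def _old_ll(self, rho, f, crit):
        R = ndtr(rho)  # (p, c)
        cum = ndtr(crit[:, None, :] - f[:, :, None])  # (p, c, 5)
        p_old = np.empty(cum.shape[:2] + (N_BINS,))
        p_old[..., 0] = cum[..., 0]
        p_old[..., 1:-1] = np.diff(cum, axis=-1)
        p_old[..., -1] = 1.0 - cum[..., -1]
        p_old *= (1.0 - R)[..., None]
        p_old[..., -1] += R
        np.clip(p_old, 1e-300, None, out=p_old)
        return np.einsum("pcb,pcb->pc", self.counts[:, :, 0].astype(float), np.log(p_old))

    def _new_ll(self, crit):
        cum = ndtr(crit)  # (p, 5)
        p_new = np.empty((crit.shape[0], N_BINS))
        p_new[:, 0] = cum[:, 0]
        p_new[:, 1:-1] = np.diff(cum, axis=-1)
        p_new[:, -1] = 1.0 - cum[:, -1]
        np.clip(p_new, 1e-300, None, out=p_new)
        return np.einsum("pcb,pb->pc", self.counts[:, :, 1].astype(float), np.log(p_new))

    # ------------------------------------------------------------------ #
    def _initial_state(self, rng):
        """Data-driven starting values with per-chain jitter."""
        counts = self.counts.astype(float)
        n_p = counts.shape[0]
        n_old = counts[:, :, 0].sum(-1)
        n_new = counts[:, :, 1].sum(-1)
        if np.any(n_old == 0) or np.any(n_new == 0):
            raise ValueError("every participant x condition cell needs old and new trials")

        # criteria from pooled new-response cumulative proportions
        new_pool = counts[:, :, 1].sum(axis=1)  # (p, 6)
        cum = np.cumsum(new_pool, axis=1)[:, :-1] / new_pool.sum(axis=1, keepdims=True)
        cum = np.clip(cum, 0.02, 0.98)
        cum = np.maximum.accumulate(cum + 1e-4 * np.arange(1, _N_CRIT + 1), axis=1)
        crit0 = ndtri(np.clip(cum, 0.02, 0.99))
        gamma = np.empty((n_p, _N_CRIT))
        gamma[:, 0] = crit0[:, 0]
        gamma[:, 1:] = np.log(np.clip(np.diff(crit0, axis=1), 0.05, None))

        p6_old = counts[:, :, 0, -1] / n_old
        p6_new = counts[:, :, 1, -1] / n_new
        rho = ndtri(np.clip(p6_old - p6_new, 0.02, 0.90))
        hit = np.clip(counts[:, :, 0, 3:].sum(-1) / n_old, 0.05, 0.98)
        fa = np.clip(counts[:, :, 1, 3:].sum(-1) / n_new, 0.02, 0.95)
        f = np.clip(ndtri(hit) - ndtri(fa), -0.5, 3.0)

        rho = rho + rng.normal(0, 0.05, rho.shape)
        f = f + rng.normal(0, 0.05, f.shape)
        gamma = gamma + rng.normal(0, 0.05, gamma.shape)
        state = {
            "rho": rho,
            "f": f,
            "gamma": gamma,
            "mu_r": rho.mean(axis=0),
            "mu_f": f.mean(axis=0),
            "mu_g": gamma.mean(axis=0),
            "log_sig_r": np.log(np.clip(rho.std(), 0.05, 1.0)),
            "log_sig_f": np.log(np.clip(f.std(), 0.05, 1.0)),
            "log_sig_g": np.log(np.clip(gamma.std(axis=0), 0.05, 1.0)),
        }
        return state

    def _run_chain(self, settings, rng, store_participants):
        pri = self.priors
        st = self._initial_state(rng)
        n_p, n_c = self.counts.shape[:2]
        rho, f, gamma = st["rho"], st["f"], st["gamma"]
        mu_r, mu_f, mu_g = st["mu_r"], st["mu_f"], st["mu_g"]
        log_sig_r, log_sig_f = st["log_sig_r"], st["log_sig_f"]
        log_sig_g = st["log_sig_g"]

        crit = _criteria_from_gamma(gamma)
        old_ll = self._old_ll(rho, f, crit)
        new_ll = self._new_ll(crit)

        # adaptive proposal scales (log)
        ls_rho = np.full((n_p, n_c), np.log(0.3))
        ls_f = np.full((n_p, n_c), np.log(0.3))
        ls_joint = np.full((n_p, n_c), np.log(0.3))
        ls_gam = np.full((n_p, _N_CRIT), np.log(0.1))
        ls_sig = np.full(2 + _N_CRIT, np.log(0.2))  # sig_r, sig_f, sig_g[k]

        total = settings.warmup + settings.draws
        out = {
            "mu_r": np.empty((settings.draws, n_c)),
            "mu_f": np.empty((settings.draws, n_c)),
            "mu_g": np.empty((settings.draws, _N_CRIT)),
            "sigma_r": np.empty(settings.draws),
            "sigma_f": np.empty(settings.draws),
            "sigma_g": np.empty((settings.draws, _N_CRIT)),
        }
        if store_participants:
            out["R"] = np.empty((settings.draws, n_p, n_c), dtype=np.float32)
            out["F"] = np.empty((settings.draws, n_p, n_c), dtype=np.float32)
        crit_sum = np.zeros((n_p, _N_CRIT))

        target = 0.44
        for t in range(total):
            adapting = t < settings.warmup
            rate = min(0.05, 2.0 * (t + 1) ** -0.6) if adapting else 0.0
            sig_r, sig_f = np.exp(log_sig_r), np.exp(log_sig_f)
            sig_g = np.exp(log_sig_g)

            for _ in range(settings.rf_sweeps):
                # --- rho (recollection, probit scale), per (i, j) cell
                prop = rho + np.exp(ls_rho) * rng.standard_normal((n_p, n_c))
                ll_prop = self._old_ll(prop, f, crit)
                dprior = ((rho - mu_r) ** 2 - (prop - mu_r) ** 2) / (2 * sig_r**2)
                acc = np.log(rng.random((n_p, n_c))) < ll_prop - old_ll + dprior
                rho = np.where(acc, prop, rho)
                old_ll = np.where(acc, ll_prop, old_ll)
                if adapting:
                    ls_rho += rate * (acc - target)

                # --- f (familiarity), per (i, j) cell -----------------
                prop = f + np.exp(ls_f) * rng.standard_normal((n_p, n_c))
                ll_prop = self._old_ll(rho, prop, crit)
                dprior = ((f - mu_f) ** 2 - (prop - mu_f) ** 2) / (2 * sig_f**2)
                acc = np.log(rng.random((n_p, n_c))) < ll_prop - old_ll + dprior
                f = np.where(acc, prop, f)
                old_ll = np.where(acc, ll_prop, old_ll)
                if adapting:
                    ls_f += rate * (acc - target)

                # --- joint anti-correlated (rho, f) move --------------
                # the old-class likelihood trades R off against F; a move
                # along (+rho, -f) crosses the ridge faster than scalar
                # updates.
                delta = np.exp(ls_joint) * rng.standard_normal((n_p, n_c))
                prop_rho, prop_f = rho + delta, f - 0.6 * delta
                ll_prop = self._old_ll(prop_rho, prop_f, crit)
                dprior = (
                    (rho - mu_r) ** 2 - (prop_rho - mu_r) ** 2
                ) / (2 * sig_r**2) + ((f - mu_f) ** 2 - (prop_f - mu_f) ** 2) / (2 * sig_f**2)
                acc = np.log(rng.random((n_p, n_c))) < ll_prop - old_ll + dprior
                rho = np.where(acc, prop_rho, rho)
                f = np.where(acc, prop_f, f)
                old_ll = np.where(acc, ll_prop, old_ll)
                if adapting:
                    ls_joint += rate * (acc - target)

            # --- criteria coordinates, per participant ----------------
            for k in range(_N_CRIT):
                gam_prop = gamma.copy()
                gam_prop[:, k] += np.exp(ls_gam[:, k]) * rng.standard_normal(n_p)
                crit_prop = _criteria_from_gamma(gam_prop)
                old_prop = self._old_ll(rho, f, crit_prop)
                new_prop = self._new_ll(crit_prop)
                delta = (old_prop - old_ll).sum(axis=1) + (new_prop - new_ll).sum(axis=1)
                delta += ((gamma[:, k] - mu_g[k]) ** 2 - (gam_prop[:, k] - mu_g[k]) ** 2) / (
                    2 * sig_g[k] ** 2
                )
                acc = np.log(rng.random(n_p)) < delta
                gamma[acc, k] = gam_prop[acc, k]
                crit[acc] = crit_prop[acc]
                old_ll[acc] = old_prop[acc]
                new_ll[acc] = new_prop[acc]
                if adapting:
                    ls_gam[:, k] += rate * (acc - target)

            # --- population means: conjugate Gibbs --------------------
            for mu, vals, sig in (
                (mu_r, rho, sig_r),
                (mu_f, f, sig_f),
            ):
                prec = n_p / sig**2 + 1.0 / pri.mu_sd**2
                mean = vals.sum(axis=0) / sig**2 / prec
                mu[:] = mean + rng.standard_normal(mu.shape) / np.sqrt(prec)
            prec = n_p / sig_g**2 + 1.0 / pri.mu_sd**2
            mean = gamma.sum(axis=0) / sig_g**2 / prec
            mu_g[:] = mean + rng.standard_normal(_N_CRIT) / np.sqrt(prec)

            # --- random-effect SDs: MH on log sigma -------------------
            def _sig_step(log_sig, resid_sq, n, slot):
                prop_ls = log_sig + np.exp(ls_sig[slot]) * rng.standard_normal(np.shape(log_sig))
                cur_s, prop_s = np.exp(log_sig), np.exp(prop_ls)
                # likelihood + HalfNormal(scale) prior + log-Jacobian
                d = (
                    -n * (prop_ls - log_sig)
                    - resid_sq / 2 * (1 / prop_s**2 - 1 / cur_s**2)
                    - (prop_s**2 - cur_s**2) / (2 * pri.sigma_scale**2)
                    + (prop_ls - log_sig)
                )
                acc = np.log(rng.random(np.shape(d))) < d
                new_ls = np.where(acc, prop_ls, log_sig)
                if adapting:
                    ls_sig[slot] += rate * (np.asarray(acc, dtype=float) - target)
                return new_ls

            log_sig_r = float(_sig_step(log_sig_r, ((rho - mu_r) ** 2).sum(), n_p * n_c, 0))
            log_sig_f = float(_sig_step(log_sig_f, ((f - mu_f) ** 2).sum(), n_p * n_c, 1))
            log_sig_g = _sig_step(log_sig_g, ((gamma - mu_g) ** 2).sum(axis=0), n_p, slice(2, None))

            # --- parameter-expansion rescale: jointly scale the random
            # effects and their SD to cross the funnel (deterministic
            # expansion move; log-ratio = delta-loglik + eps - delta
            # half-normal prior).
            for which in ("r", "f"):
                eps = 0.3 * rng.standard_normal()
                scale = np.exp(eps)
                if which == "r":
                    prop_vals = mu_r + (rho - mu_r) * scale
                    ll_prop = self._old_ll(prop_vals, f, crit)
                    cur_sig = np.exp(log_sig_r)
                else:
                    prop_vals = mu_f + (f - mu_f) * scale
                    ll_prop = self._old_ll(rho, prop_vals, crit)
                    cur_sig = np.exp(log_sig_f)
                prop_sig = cur_sig * scale
                logr = (
                    (ll_prop - old_ll).sum()
                    + eps
                    - (prop_sig**2 - cur_sig**2) / (2 * pri.sigma_scale**2)
                )
                if np.log(rng.random()) < logr:
                    old_ll = ll_prop
                    if which == "r":
                        rho = prop_vals
                        log_sig_r = float(log_sig_r + eps)
                    else:
                        f = prop_vals
                        log_sig_f = float(log_sig_f + eps)

            if not adapting:
                d = t - settings.warmup
                out["mu_r"][d] = mu_r
                out["mu_f"][d] = mu_f
                out["mu_g"][d] = mu_g
                out["sigma_r"][d] = np.exp(log_sig_r)
                out["sigma_f"][d] = np.exp(log_sig_f)
                out["sigma_g"][d] = np.exp(log_sig_g)
                if store_participants:
                    out["R"][d] = ndtr(rho)
                    out["F"][d] = f
                crit_sum += crit
        out["crit_mean"] = crit_sum / settings.draws
        return out

    # ------------------------------------------------------------------ #
    def fit(
        self,
        preset: str | SamplerSettings = "test",
        seed: int = 0,
        store_participants: bool = True,
    ) -> "DPSDResults":
        """Run the MCMC sampler and return a results object.

        Parameters
        ----------
        preset : str or SamplerSettings
            ``"full"`` (4 x 12,000/12,000), ``"acceptance"`` (4 x
            2,000/2,000) or ``"test"`` (4 x 1,000/1,000), or explicit
            settings.
        seed : int
            Root seed; chains receive independent spawned streams.
        store_participants : bool
            Keep participant-level R/F draws (samples x participants x
            conditions) in the results.
        """
        settings = PRESETS[preset] if isinstance(preset, str) else preset
        rngs = spawn_rngs(seed, settings.chains)
        chains = [self._run_chain(settings, rng, store_participants) for rng in rngs]
        draws = {
            key: np.stack([ch[key] for ch in chains]) for key in chains[0]
        }
        return DPSDResults(self, settings, draws)


class DPSDResults:
    """Posterior draws, diagnostics and summaries of a hierarchical DPSD fit.

    Population-level recollection/familiarity are summarized from the
    fixed-effect chains by default (``population="fixed"``: R draws are
    ``probit^{-1}`` of the population-mean chain); ``population="participant_mean"``
    instead averages the participant-level draws per sample.
    """

    def __init__(self, model: HierarchicalDPSD, settings: SamplerSettings, draws: dict):
        self.model = model
        self.settings = settings
        self.draws = draws

    # ------------------------------------------------------------------ #
    def population_draws(self, parameter: str, population: str = "fixed") -> np.ndarray:
        """Draws of population-level R or F, shape (chains, draws, conditions)."""
        if parameter not in ("R", "F"):
            raise ValueError("parameter must be 'R' or 'F'")
        if population == "fixed":
            if parameter == "R":
                return ndtr(self.draws["mu_r"])
            return self.draws["mu_f"]
        if population == "participant_mean":
            if parameter not in self.draws:
                raise ValueError("participant-level draws were not stored")
            return self.draws[parameter].mean(axis=2)
        raise ValueError("population must be 'fixed' or 'participant_mean'")

    def population_summary(self, population: str = "fixed") -> dict[str, PosteriorSummary]:
        out = {}
        for par in ("R", "F"):
            arr = self.population_draws(par, population)
            for j, cond in enumerate(self.model.conditions):
                out[f"{par}[{cond}]"] = summarize_posterior(arr[:, :, j])
        return out

    def summary(self, population: str = "fixed") -> pd.DataFrame:
        """Posterior summary table for all population-level parameters."""
        rows = {}
        rows.update(self.population_summary(population))
        for j in range(_N_CRIT):
            crit_draws = _criteria_from_gamma(self.draws["mu_g"])
            rows[f"c{j + 1}"] = summarize_posterior(crit_draws[:, :, j])
        rows["sigma_R"] = summarize_posterior(self.draws["sigma_r"])
        rows["sigma_F"] = summarize_posterior(self.draws["sigma_f"])
        df = pd.DataFrame(
            {
                "mean": {k: s.mean for k, s in rows.items()},
                "hdi_2.5%": {k: s.hdi_lo for k, s in rows.items()},
                "hdi_97.5%": {k: s.hdi_hi for k, s in rows.items()},
                "rhat": {k: s.rhat for k, s in rows.items()},
                "ess": {k: s.ess for k, s in rows.items()},
            }
        )
        df.index.name = "parameter"
        return df

    @property
    def converged(self) -> bool:
        """True when every population-level parameter has R-hat <= 1.1."""
        summ = self.population_summary()
        return all(s.rhat <= _RHAT_FLAG for s in summ.values())

    def check_convergence(self) -> bool:
        ok = self.converged
        if not ok:
            warnings.warn(
                "MCMC non-convergence: population-level R-hat exceeds "
                f"{_RHAT_FLAG}; increase warmup/draws", RuntimeWarning,
            )
        return ok

    # ------------------------------------------------------------------ #
    def participant_params(self) -> pd.DataFrame:
        """Posterior-mean participant-level DPSD parameters (long format)."""
        if "R" not in self.draws:
            raise ValueError("participant-level draws were not stored")
        R = self.draws["R"].mean(axis=(0, 1))
        F = self.draws["F"].mean(axis=(0, 1))
        rows = []
        for i, pid in enumerate(self.model.participants):
            for j, cond in enumerate(self.model.conditions):
                rows.append({"participant": pid, "condition": cond,
                             "R": float(R[i, j]), "F": float(F[i, j])})
        return pd.DataFrame(rows)

    def participant_criteria(self) -> np.ndarray:
        """Posterior-mean criteria per participant, shape (participants, 5).

        The model shares criteria across conditions within a participant.
        """
        return self.draws["crit_mean"].mean(axis=0)

    def plot_fit(self, trials=None, **kwargs):
        from wmcda.dpsd.plotting import plot_fit

        return plot_fit(self, trials=trials, **kwargs)


def fit_hierarchical(
    trials: pd.DataFrame,
    preset: str | SamplerSettings = "test",
    seed: int = 0,
    priors: DPSDPriors | None = None,
    **from_df_kwargs,
) -> DPSDResults:
    """Fit the hierarchical DPSD model to a binned trial table.

    Thin functional wrapper around
    ``HierarchicalDPSD.from_dataframe(...).fit(...)``.
    """
    model = HierarchicalDPSD.from_dataframe(trials, priors=priors, **from_df_kwargs)
    results = model.fit(preset=preset, seed=seed)
    results.check_convergence()
    return results
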