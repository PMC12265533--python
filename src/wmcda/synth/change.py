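"""Fixed-capacity observer for single-probe change detection.

On each trial the probed item is "in memory" with probability
``min(K/N, 1)`` for set size ``N``.  In-memory probes are answered
correctly; otherwise the observer guesses "change" with the guess rate.
An optional lapse rate replaces the response with a coin flip.  Applying
``K = N * (H - FA)`` to this observer's data recovers ``min(K, N)`` in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from wmcda._utils import check_probability

__all__ = ["CapacityObserverSpec", "gen_change_detection"]


@dataclass(frozen=True)
class CapacityObserverSpec:
    """Generative conditions for the lateralized change-detection task.

    ``capacity`` may be a single value or a mapping from stimulus type to
    capacity (e.g. a higher effective K for trial-unique objects).
    Defaults follow the EEG experiment's design: set sizes 1/3/5, 200
    trials per cell, 25 participants; ``capacity_sd`` spreads true
    capacities across participants (truncated at 0).
    """

    capacity: float | Mapping[str, float] = 3.0
    set_sizes: tuple[int, ...] = (1, 3, 5)
    guess_rate: float = 0.5
    lapse_rate: float = 0.0
    n_participants: int = 25
    n_trials_per_cell: int = 200
    capacity_sd: float = 0.0
    p_change: float = 0.5
    seed: int = 0

    def __post_init__(self):
        caps = self.capacity.values() if isinstance(self.capacity, Mapping) else [self.capacity]
        for k in caps:
            if k < 0:
                raise ValueError(f"capacity must be >= 0, got {k!r}")
        check_probability(self.guess_rate, "guess_rate")
        check_probability(self.lapse_rate, "lapse_rate")
        check_probability(self.p_change, "p_change")
        if self.capacity_sd < 0:
            raise ValueError("capacity_sd must be >= 0")

    @property
    def stim_types(self) -> tuple[str, ...]:
        if isinstance(self.capacity, Mapping):
            return tuple(self.capacity)
        return ("CLR_REP",)

    def capacity_of(self, stim_type: str) -> float:
        if isinstance(self.capacity, Mapping):
            return float(self.capacity[stim_type])
        return float(self.capacity)


def gen_change_detection(spec: CapacityObserverSpec) -> pd.DataFrame:
    """Simulate change-detection trials from the fixed-capacity observer.

    Returns
    -------
    DataFrame with columns ``participant``, ``stim_type``, ``set_size``,
    ``change`` (bool ground truth), ``response_change`` (bool), plus the
    recognition-style aliases ``probe_status`` ('old' = change trial) and
    ``old_response`` so :func:`wmcda.behavior.compute_rates` applies
    directly.  Change/no-change trial counts split evenly per cell.
    """
    rng = np.random.default_rng(spec.seed)
    n_change = int(round(spec.n_trials_per_cell * spec.p_change))
    n_same = spec.n_trials_per_cell - n_change

    frames = []
    for i in range(spec.n_participants):
        for stim in spec.stim_types:
            k_i = spec.capacity_of(stim)
            if spec.capacity_sd > 0:
                k_i = max(0.0, k_i + rng.normal(0.0, spec.capacity_sd))
            for n in spec.set_sizes:
                change = np.concatenate([np.ones(n_change, bool), np.zeros(n_same, bool)])
                m = min(k_i / n, 1.0)
                in_memory = rng.random(change.size) < m
                guesses = rng.random(change.size) < spec.guess_rate
                resp = np.where(in_memory, change, guesses)
                if spec.lapse_rate > 0:
                    lapse = rng.random(change.size) < spec.lapse_rate
                    resp = np.where(lapse, rng.random(change.size) < 0.5, resp)
                frames.append(
                    pd.DataFrame(
                        {
                            "participant": i,
                            "stim_type": stim,
                            "set_size": n,
                            "change": change,
                            "response_change": resp.astype(bool),
                        }
                    )
                )
    df = pd.concat(frames, ignore_index=True)
    df["probe_status"] = np.where(df["change"], "old", "new")
    df["old_response"] = df["response_change"]
    return df
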