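"""Shared constants and small helpers."""

from __future__ import annotations

import numpy as np

#: Stimulus-type conditions of the recognition experiment:
#: trial-repeated colors, trial-repeated objects, trial-unique objects.
CONDITIONS = ("CLR_REP", "OBJ_REP", "OBJ_UNI")

#: Number of confidence bins (1 = surely-new ... 6 = surely-old).
N_BINS = 6

#: Lateral posterior electrode pairs (left, right) entering the CDA.
CDA_PAIRS = (("P3", "P4"), ("P7", "P8"), ("PO3", "PO4"), ("PO7", "PO8"))

#: All channels required for CDA computation.
CDA_CHANNELS = tuple(ch for pair in CDA_PAIRS for ch in pair)


def spawn_rngs(seed: int | np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent generators from one root seed."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in root.spawn(n)]


def check_probability(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    return float(value)


def check_increasing(values, name: str):
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or not np.all(np.diff(arr) > 0):
        raise ValueError(f"{name} must be strictly increasing, got {values!r}")
    return arr
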