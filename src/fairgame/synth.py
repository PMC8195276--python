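"""Synthetic random-play sessions and the Monte-Carlo validation of pattern counting.

The sliding-window counter could in principle under-count multi-trial
patterns (exchange needs two trials to show) relative to single-trial ones
(a mutual rush shows in one row).  The validation here checks that it does
not: generate many sequences of two iid random players (each avoiding with
probability 0.5 per trial), count patterns, and compare the mean counts with
the exact expectations from exhaustive enumeration (3.75 mutual avoid, 3.75
mutual rush, 7.5 exchange per 48 windows).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .patterns import LABELS, WINDOW_LENGTH, WindowLabel, label_lookup_table

__all__ = ["MonteCarloSpec", "MonteCarloResult", "random_session", "run_montecarlo"]


def random_session(
    n: int,
    p1: float = 0.5,
    p2: float = 0.5,
    seed: Optional[int] = None,
) -> np.ndarray:
    """(n, 2) matrix of iid Bernoulli action codes, independent streams per player.

    Column i holds player i's actions; avoid=1 is drawn with probability p_i.
    """
    if n < 1:
        raise ValueError("need at least one trial")
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    seq1, seq2 = np.random.SeedSequence(seed).spawn(2)
    col1 = (np.random.default_rng(seq1).random(n) < p1).astype(np.int64)
    col2 = (np.random.default_rng(seq2).random(n) < p2).astype(np.int64)
    return np.column_stack([col1, col2])


@dataclass(frozen=True)
class MonteCarloSpec:
    """Replication design for the random-play validation (defaults match the
    reference study: 10,000 replicates of 50 trials at p(avoid)=0.5 each)."""

    replicates: int = 10_000
    trials_per_replicate: int = 50
    p_avoid_player1: float = 0.5
    p_avoid_player2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.trials_per_replicate < 1:
            raise ValueError("need at least one trial per replicate")
        for p in (self.p_avoid_player1, self.p_avoid_player2):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class MonteCarloResult:
    """Mean and standard deviation of per-replicate window counts, per label."""

    spec: MonteCarloSpec
    mean: dict[WindowLabel, float]
    sd: dict[WindowLabel, float]
    counts: Optional[np.ndarray] = None  # (replicates, n_labels) when retained

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [label.value for label in LABELS],
                "mean": [self.mean[label] for label in LABELS],
                "sd": [self.sd[label] for label in LABELS],
            }
        )


def run_montecarlo(
    spec: MonteCarloSpec = MonteCarloSpec(), keep_counts: bool = False
) -> MonteCarloResult:
    """Replicate random play and count patterns; report per-label mean and sd.

    Each replicate draws its own child seed from the master seed by a fixed
    spawning scheme, so results are reproducible and independent of any
    batching.  Classification goes through the same 64-entry lookup table
    that backs count_patterns (single phase: windows of 3, step 1).
    """
    n = spec.trials_per_replicate
    n_windows = max(n - WINDOW_LENGTH + 1, 0)
    table = label_lookup_table()
    root = np.random.SeedSequence(spec.seed)
    child_seeds = root.spawn(spec.replicates)

    all_counts = np.zeros((spec.replicates, len(LABELS)), dtype=np.int64)
    for rep, child in enumerate(child_seeds):
        s1, s2 = child.spawn(2)
        col1 = (np.random.default_rng(s1).random(n) < spec.p_avoid_player1).astype(np.int64)
        col2 = (np.random.default_rng(s2).random(n) < spec.p_avoid_player2).astype(np.int64)
        codes = 2 * col1 + col2
        if n_windows:
            labels = table[codes[:-2], codes[1:-1], codes[2:]]
            all_counts[rep] = np.bincount(labels, minlength=len(LABELS))

    mean = all_counts.mean(axis=0)
    sd = all_counts.std(axis=0, ddof=0)
    return MonteCarloResult(
        spec=spec,
        mean={label: float(m) for label, m in zip(LABELS, mean)},
        sd={label: float(s) for label, s in zip(LABELS, sd)},
        counts=all_counts if keep_counts else None,
    )
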