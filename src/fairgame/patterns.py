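"""Bilateral behavioral-pattern classification of joint-action sequences.

Sessions are analyzed through a sliding window of 3 consecutive trials
(step 1, restarted at every phase boundary).  Each window is assigned one of
five labels based on the *consecutive pairs* of joint outcomes it contains:

====================  =====================================================
label                 defining consecutive pair
====================  =====================================================
mutual_avoid          (AA, AA) — both players avoided twice running
mutual_rush           (RR, RR) — both players rushed twice running
exchange              (AR, RA) or (RA, AR) — one-sided outcomes, swapped
unfair                (AR, AR) or (RA, RA) — one exploits, the other yields
====================  =====================================================

A window gets label P iff it contains a defining pair for P and no defining
pair for any other pattern; windows matching two patterns are discarded as
*undefined* rather than resolved by precedence.  Two extra vetoes keep the
mutual labels honest: a mutual_avoid window must contain no RR row, and a
mutual_rush window no AA row.  Under iid uniform play this rule gives exact
per-window label probabilities 5/64 (mutual_avoid), 5/64 (mutual_rush),
10/64 (exchange) — i.e. expected counts 3.75 / 3.75 / 7.5 per 48 windows.
"""

from __future__ import annotations

import warnings
from enum import Enum
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .game import Action, JointOutcome

__all__ = [
    "WindowLabel",
    "WINDOW_LENGTH",
    "classify_window",
    "label_lookup_table",
    "count_patterns",
    "counts_from_log",
    "enumerate_label_distribution",
    "score_trace",
    "phase_slope",
]

#: window length in trials; the defaults of the reference design
WINDOW_LENGTH = 3


class WindowLabel(str, Enum):
    MUTUAL_AVOID = "mutual_avoid"
    MUTUAL_RUSH = "mutual_rush"
    EXCHANGE = "exchange"
    UNFAIR = "unfair"
    UNDEFINED = "undefined"


#: canonical label order for tables
LABELS = tuple(WindowLabel)

_PAIR_PATTERN = {
    ("AA", "AA"): WindowLabel.MUTUAL_AVOID,
    ("RR", "RR"): WindowLabel.MUTUAL_RUSH,
    ("AR", "RA"): WindowLabel.EXCHANGE,
    ("RA", "AR"): WindowLabel.EXCHANGE,
    ("AR", "AR"): WindowLabel.UNFAIR,
    ("RA", "RA"): WindowLabel.UNFAIR,
}


def classify_window(rows: Sequence[JointOutcome]) -> WindowLabel:
    """Label a window of 3 consecutive joint outcomes.

    Deterministic and exhaustive: every one of the 64 possible windows maps
    to exactly one label.  Swapping the two players everywhere (AR <-> RA)
    leaves the label unchanged.
    """
    if len(rows) != WINDOW_LENGTH:
        raise ValueError(f"window must have exactly {WINDOW_LENGTH} rows, got {len(rows)}")
    codes = [JointOutcome(*row).code for row in rows]
    matched = {
        _PAIR_PATTERN[pair]
        for pair in zip(codes, codes[1:])
        if pair in _PAIR_PATTERN
    }
    if len(matched) != 1:
        return WindowLabel.UNDEFINED
    label = matched.pop()
    # a window cannot be "mutually avoiding" if the players also crashed in it,
    # nor "mutually rushing" if they also jointly conceded
    if label is WindowLabel.MUTUAL_AVOID and "RR" in codes:
        return WindowLabel.UNDEFINED
    if label is WindowLabel.MUTUAL_RUSH and "AA" in codes:
        return WindowLabel.UNDEFINED
    return label


def _all_outcomes() -> list[JointOutcome]:
    return [
        JointOutcome(a, b)
        for a, b in product((Action.AVOID, Action.RUSH), repeat=2)
    ]


def label_lookup_table() -> np.ndarray:
    """(4, 4, 4) array mapping outcome-code triples to label indices in LABELS.

    Outcome codes are 2*self + opponent with rush=0/avoid=1 (so AA=3, AR=2,
    RA=1, RR=0).  Built by running every triple through classify_window, so
    vectorized consumers share the scalar classifier's behavior exactly.
    """
    table = np.empty((4, 4, 4), dtype=np.int8)
    outcomes = {2 * int(o.self_action) + int(o.opponent_action): o for o in _all_outcomes()}
    for i, j, k in product(range(4), repeat=3):
        label = classify_window([outcomes[i], outcomes[j], outcomes[k]])
        table[i, j, k] = LABELS.index(label)
    return table


def enumerate_label_distribution() -> dict[WindowLabel, float]:
    """Exact label probabilities under iid uniform play, by brute-force enumeration.

    All 64 outcome triples are equally likely when both players draw
    avoid/rush at p = 0.5 independently; each is pushed through
    classify_window and the relative frequencies returned (they sum to 1).
    """
    counts = {label: 0 for label in LABELS}
    triples = list(product(_all_outcomes(), repeat=WINDOW_LENGTH))
    for triple in triples:
        counts[classify_window(triple)] += 1
    return {label: c / len(triples) for label, c in counts.items()}


def _phase_slices(n: int, phase_lengths: Sequence[int]) -> list[slice]:
    if sum(phase_lengths) != n:
        raise ValueError(
            f"phase lengths {list(phase_lengths)} do not sum to the {n} trials"
        )
    slices, start = [], 0
    for length in phase_lengths:
        slices.append(slice(start, start + length))
        start += length
    return slices


def count_patterns(
    actions: np.ndarray, phase_lengths: Sequence[int]
) -> pd.DataFrame:
    """Count window labels per phase.

    Parameters
    ----------
    actions : (n, 2) integer array of action codes (rush=0/avoid=1), one
        player per column.
    phase_lengths : trials per phase, summing to n.  Windows slide by one
        trial within a phase and never span a boundary, so a phase of L
        trials contributes L-2 windows (0 if L < 3, with a warning).

    Returns
    -------
    DataFrame indexed by 1-based phase, one column per label plus
    ``n_windows``; each row's label counts sum to its n_windows.
    """
    actions = np.asarray(actions, dtype=np.int64)
    if actions.ndim != 2 or actions.shape[1] != 2:
        raise ValueError("actions must be an (n, 2) array")
    if not np.isin(actions, (0, 1)).all():
        raise ValueError("action codes must be 0 (rush) or 1 (avoid)")

    table = label_lookup_table()
    codes = 2 * actions[:, 0] + actions[:, 1]
    rows = []
    for phase_idx, sl in enumerate(_phase_slices(len(actions), phase_lengths), start=1):
        phase_codes = codes[sl]
        if len(phase_codes) < WINDOW_LENGTH:
            warnings.warn(
                f"phase {phase_idx} has {len(phase_codes)} trials "
                f"(< {WINDOW_LENGTH}): zero windows",
                stacklevel=2,
            )
            label_idx = np.empty(0, dtype=np.int8)
        else:
            label_idx = table[phase_codes[:-2], phase_codes[1:-1], phase_codes[2:]]
        counts = np.bincount(label_idx, minlength=len(LABELS))
        rows.append(
            {
                "phase": phase_idx,
                **{label.value: int(c) for label, c in zip(LABELS, counts)},
                "n_windows": int(len(label_idx)),
            }
        )
    return pd.DataFrame(rows).set_index("phase")


def counts_from_log(log) -> pd.DataFrame:
    """Per-phase pattern counts of a recorded session."""
    return count_patterns(log.actions(), log.config.phase_lengths)


def score_trace(log) -> pd.DataFrame:
    """Per-iteration cumulative scores of both players, starting from the endowment."""
    frame = log.to_frame()
    return frame[["iteration", "phase", "agent_cum", "opponent_cum"]].set_index(
        "iteration"
    )


def phase_slope(
    trace: pd.DataFrame, phase: int, column: str = "agent_cum"
) -> float:
    """Score slope of a phase in points per iteration.

    Defined as (last score of the phase - first score of the phase) divided
    by the phase length — the divisor is the full phase length, not the
    number of first-to-last differences.
    """
    block = trace[trace["phase"] == phase]
    if block.empty:
        raise ValueError(f"phase {phase} not present in trace")
    return float(block[column].iloc[-1] - block[column].iloc[0]) / len(block)
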