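"""Gambling-session trial design with exact-frequency outcome realization.

Each trial is a target gamble with a nominal win probability P in
{0, .25, .50, .75, 1} for winning +-1 GBP.  Outcomes are realized by
stratified assignment: among the N gambles at win probability P, exactly
N*P are wins, so realized frequencies match the nominal probabilities in
every session.  An i.i.d. Bernoulli mode is available behind a flag for
sensitivity analyses.

Conditions for analysis are labeled by the probability of the *realized*
outcome: a loss after a .25-win gamble is a P = .75 loss, giving the
2 (valence) x 4 (outcome probability .25/.50/.75/1) design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_GAMBLE_COUNTS", "build_session_design"]

#: per-win-probability target gamble counts of the full 540-trial session
#: (45 certain wins, 45 certain losses, 90 even gambles, 180 at each of
#: .25 and .75)
DEFAULT_GAMBLE_COUNTS: dict[float, int] = {
    0.0: 45,
    0.25: 180,
    0.50: 90,
    0.75: 180,
    1.0: 45,
}

#: default number of experimental blocks (60 trials each at default counts)
DEFAULT_N_BLOCKS = 9


def build_session_design(
    counts_per_win_prob: dict[float, int] | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    seed: int | np.random.SeedSequence = 0,
    outcome_mode: str = "exact",
    outcome_onset_ms: float = 0.0,
    amount_gbp: float = 1.0,
) -> pd.DataFrame:
    """Build a randomized session trial table.

    Parameters
    ----------
    counts_per_win_prob
        Mapping win probability -> number of target gambles.  Counts must
        divide evenly into ``n_blocks`` and, in ``"exact"`` mode, each
        count * P must be an integer.
    outcome_mode
        ``"exact"`` (stratified assignment; realized win frequencies equal
        nominal exactly) or ``"bernoulli"`` (i.i.d. draws).

    Returns
    -------
    DataFrame with one row per trial: trial_id, block, target_win_prob,
    outcome_valence, outcome_prob, outcome_amount, outcome_onset_ms.
    """
    if counts_per_win_prob is None:
        counts_per_win_prob = DEFAULT_GAMBLE_COUNTS
    if outcome_mode not in ("exact", "bernoulli"):
        raise ValueError(f"unknown outcome_mode {outcome_mode!r}")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)

    strata = []
    for p, n in sorted(counts_per_win_prob.items()):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"win probability {p} outside [0, 1]")
        if n <= 0 or n % n_blocks != 0:
            raise ValueError(
                f"count {n} at win probability {p} is not divisible into "
                f"{n_blocks} blocks"
            )
        n_wins_f = n * p
        if outcome_mode == "exact" and abs(n_wins_f - round(n_wins_f)) > 1e-9:
            raise ValueError(
                f"exact-frequency realization impossible: {n} gambles at "
                f"P={p} imply a non-integer expected win count {n_wins_f}"
            )
        if outcome_mode == "exact":
            n_wins = int(round(n_wins_f))
            wins = np.zeros(n, dtype=bool)
            wins[:n_wins] = True
            rng.shuffle(wins)
        else:
            wins = rng.random(n) < p
        per_block = n // n_blocks
        blocks = np.repeat(np.arange(1, n_blocks + 1), per_block)
        strata.append(
            pd.DataFrame(
                {
                    "block": blocks,
                    "target_win_prob": p,
                    "outcome_valence": np.where(wins, "win", "loss"),
                }
            )
        )
    table = pd.concat(strata, ignore_index=True)

    # random trial order within each block
    order = np.concatenate(
        [
            rng.permutation(np.flatnonzero(table["block"].to_numpy() == b))
            for b in range(1, n_blocks + 1)
        ]
    )
    table = table.iloc[order].reset_index(drop=True)

    is_win = table["outcome_valence"].to_numpy() == "win"
    p_target = table["target_win_prob"].to_numpy()
    table["outcome_prob"] = np.where(is_win, p_target, 1.0 - p_target)
    table["outcome_amount"] = np.where(is_win, amount_gbp, -amount_gbp)
    table["outcome_onset_ms"] = outcome_onset_ms
    table.insert(0, "trial_id", np.arange(len(table)))
    return table[
        [
            "trial_id",
            "block",
            "target_win_prob",
            "outcome_valence",
            "outcome_prob",
            "outcome_amount",
            "outcome_onset_ms",
        ]
    ]
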