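"""SRTT performance metrics: RT cleaning, offline gains and the TMR index.

Performance speed is the mean correct reaction time (RT, ms) per practice
block.  The offline change in performance between a pre-sleep plateau and a
post-sleep retest is expressed in percent, positive when the participant
got faster::

    change% = 100 * (RT_pre - RT_post) / RT_pre

and the TMR index is the difference in offline change between the
reactivated and non-reactivated sequence, averaged over the post-nap and
post-night retests.  Blocks are aggregated as mean-of-block-means so each
block weighs equally regardless of how many trials survived cleaning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "clean_rts",
    "offline_change",
    "tmr_index",
    "generation_accuracy",
    "overall_change",
]

_BLOCK_KEYS = ["participant", "session", "block"]


def clean_rts(trials: pd.DataFrame, n_sd: float = 3.0):
    """Remove correct-trial RT outliers beyond ``n_sd`` SD of their block.

    The mean and SD are computed per participant x session x block on the
    correct trials *before* any exclusion.  Incorrect trials are never
    RT-cleaned (they are excluded from speed analyses anyway).  Blocks with
    fewer than 3 correct trials are flagged and kept untouched.

    Returns ``(kept, excluded_fraction, flagged_blocks)`` where
    ``excluded_fraction`` is relative to the number of correct trials.
    """
    trials = trials.reset_index(drop=True)
    correct = trials[trials["correct"]]
    keep = np.ones(len(trials), dtype=bool)
    flagged = []
    for key, grp in correct.groupby(_BLOCK_KEYS):
        if len(grp) < 3:
            flagged.append(key)
            continue
        rt = grp["rt_ms"].to_numpy(float)
        mu, sd = rt.mean(), rt.std(ddof=1)
        if sd == 0:
            continue
        out = np.abs(rt - mu) > n_sd * sd
        keep[grp.index[out]] = False
    n_corr = len(correct)
    excluded_fraction = float((~keep).sum()) / n_corr if n_corr else 0.0
    return trials[keep], excluded_fraction, flagged


def _block_mean_rt(trials: pd.DataFrame, session: str, blocks, condition=None):
    sel = (trials["session"] == session) & trials["correct"] & trials["block"].isin(blocks)
    if condition is not None:
        sel &= trials["condition"] == condition
    sub = trials[sel]
    if sub.empty:
        raise ValueError(
            f"no correct trials for session={session!r} blocks={list(blocks)} "
            f"condition={condition!r}"
        )
    return float(sub.groupby("block")["rt_ms"].mean().mean())


def offline_change(
    trials: pd.DataFrame,
    pre_blocks=(2, 3, 4),
    post_blocks=(1, 2, 3, 4),
    pre_session: str = "pre_test",
    time_points=("post_nap", "post_night"),
) -> pd.DataFrame:
    """Offline change in speed per participant x condition x time point.

    The pre-sleep reference defaults to blocks 2-4 of the pre-nap test
    (its first block is dropped as warm-up); each retest uses its first
    four blocks.  Change is percent speedup relative to pre.
    """
    rows = []
    for p, grp in trials.groupby("participant"):
        for cond in ("reactivated", "non_reactivated"):
            pre = _block_mean_rt(grp, pre_session, pre_blocks, cond)
            for tp in time_points:
                post = _block_mean_rt(grp, tp, post_blocks, cond)
                rows.append(
                    {
                        "participant": p,
                        "condition": cond,
                        "time_point": tp,
                        "change_pct": 100.0 * (pre - post) / pre,
                    }
                )
    return pd.DataFrame(rows)


def tmr_index(changes: pd.DataFrame) -> pd.DataFrame:
    """Per-participant TMR index (% points).

    Mean over time points of (reactivated - non-reactivated) offline
    change.  Raises if any condition x time point cell is missing.
    """
    rows = []
    for p, grp in changes.groupby("participant"):
        piv = grp.pivot(index="time_point", columns="condition", values="change_pct")
        if piv.isna().any().any() or set(piv.columns) != {
            "reactivated",
            "non_reactivated",
        }:
            raise ValueError(f"participant {p}: missing condition/time-point cell")
        rows.append(
            {
                "participant": p,
                "index_pct": float(
                    (piv["reactivated"] - piv["non_reactivated"]).mean()
                ),
            }
        )
    return pd.DataFrame(rows)


def generation_accuracy(gen: pd.DataFrame, sequences: dict[str, str]) -> pd.DataFrame:
    """Percent correct ordinal positions per cued sequence and time point.

    ``gen`` rows carry participant, time_point, condition (cued sequence),
    attempt, position and key; ``sequences`` maps condition to its key
    string.  A press is correct when its key matches the cued sequence at
    that ordinal position; attempts longer/shorter than the sequence are
    scored against the overlapping positions and flagged.
    """
    rows = []
    for (p, tp, cond), grp in gen.groupby(["participant", "time_point", "condition"]):
        seq = sequences[cond]
        accs = []
        flagged = False
        for _, att in grp.groupby("attempt"):
            att = att.sort_values("position")
            m = min(len(att), len(seq))
            if len(att) != len(seq):
                flagged = True
            keys = att["key"].astype(str).to_numpy()[:m]
            target = np.array(list(seq[:m]))
            accs.append(float(np.mean(keys == target)))
        rows.append(
            {
                "participant": p,
                "time_point": tp,
                "condition": cond,
                "accuracy_pct": 100.0 * float(np.mean(accs)),
                "length_mismatch": flagged,
            }
        )
    return pd.DataFrame(rows)


def overall_change(
    trials: pd.DataFrame,
    seq_pre=("pre_train", (1, 2, 3, 4)),
    seq_post=("post_night", (13, 14, 15, 16)),
    rand_pre=("random_pre", (1, 2, 3, 4)),
    rand_post=("random_post", (1, 2, 3, 4)),
) -> pd.DataFrame:
    """Overall % speed change for the sequential vs the random SRTT.

    Sequential: first four pre-nap training blocks vs last four post-night
    blocks, conditions collapsed.  Random: the four pre vs four post random
    blocks.  A large sequential-minus-random difference indicates sequence
    learning beyond general motor improvement.
    """
    rows = []
    for p, grp in trials.groupby("participant"):
        out = {"participant": p}
        for name, (s_pre, b_pre), (s_post, b_post) in (
            ("sequential", seq_pre, seq_post),
            ("random", rand_pre, rand_post),
        ):
            pre = _block_mean_rt(grp, s_pre, b_pre)
            post = _block_mean_rt(grp, s_post, b_post)
            out[f"{name}_change_pct"] = 100.0 * (pre - post) / pre
        rows.append(out)
    return pd.DataFrame(rows)
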