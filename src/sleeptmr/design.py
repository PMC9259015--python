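"""Counterbalancing of the sound-role and sequence-condition assignments.

Three sounds fill three roles (the tone of sequence A, the tone of
sequence B, and the unassociated control tone played only during sleep),
and one of the two trained sequences is designated for reactivation.
Crossing the 3! sound-role permutations with the 2 reactivation choices
yields the 12 counterbalancing combinations participants are assigned to.
"""

from __future__ import annotations

from itertools import permutations

__all__ = ["counterbalance_assignments"]


def counterbalance_assignments(sounds=(1, 2, 3)) -> list[dict]:
    """All sound-role x sequence-condition combinations (12 for 3 sounds).

    Each entry maps the three roles to a sound and names the reactivated
    sequence.
    """
    if len(set(sounds)) != 3:
        raise ValueError("exactly three distinct sounds required")
    combos = []
    for s_a, s_b, s_ctrl in permutations(sounds):
        for reactivated in ("A", "B"):
            combos.append(
                {
                    "sound_sequence_A": s_a,
                    "sound_sequence_B": s_b,
                    "sound_control": s_ctrl,
                    "reactivated_sequence": reactivated,
                }
            )
    return combos
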