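import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleeptmr.behavior import (
    clean_rts,
    generation_accuracy,
    offline_change,
    overall_change,
    tmr_index,
)
from sleeptmr.design import counterbalance_assignments
from sleeptmr.simulate import SEQUENCE_A, SEQUENCE_B


def _trials(rows):
    return pd.DataFrame(
        rows, columns=["participant", "session", "block", "condition", "key", "correct", "rt_ms"]
    )


def _block(rts, participant=1, session="pre_test", block=1, condition="reactivated"):
    return _trials(
        [(participant, session, block, condition, "1", True, rt) for rt in rts]
    )


class TestCleanRTs:
    def test_constructed_outlier_removed(self):
        # 62 trials at 400 ms, one at 900: z(900) far beyond 3 SD
        rts = [400.0 + e for e in np.linspace(-5, 5, 62)] + [900.0]
        kept, frac, flagged = clean_rts(_block(rts))
        assert 900.0 not in kept["rt_ms"].values
        assert len(kept) == 62
        assert frac == pytest.approx(1 / 63)
        assert not flagged

    def test_zero_variance_block_untouched(self):
        kept, frac, _ = clean_rts(_block([400.0] * 20))
        assert len(kept) == 20
        assert frac == 0.0

    def test_tiny_block_flagged_and_kept(self):
        kept, frac, flagged = clean_rts(_block([400.0, 800.0]))
        assert len(kept) == 2
        assert flagged == [(1, "pre_test", 1)]

    def test_gaussian_tail_fraction_small(self):
        rng = np.random.default_rng(0)
        rows = []
        for b in range(1, 41):
            for rt in rng.normal(400, 30, size=200):
                rows.append((1, "pre_test", b, "reactivated", "1", True, rt))
        _, frac, _ = clean_rts(_trials(rows))
        # two-sided 3-SD Gaussian tail is ~0.27%
        assert frac < 0.01

    def test_incorrect_trials_not_cleaned(self):
        df = _block([400.0] * 30)
        df.loc[len(df)] = (1, "pre_test", 1, "reactivated", "1", False, 5000.0)
        kept, _, _ = clean_rts(df)
        assert 5000.0 in kept["rt_ms"].values


class TestOfflineChange:
    def _cohort(self, pre=400.0, post_nap=360.0, post_night=360.0):
        rows = []
        for cond in ("reactivated", "non_reactivated"):
            for b in (1, 2, 3, 4):
                rows += [(1, "pre_test", b, cond, "1", True, pre)] * 5
                rows += [(1, "post_nap", b, cond, "1", True, post_nap)] * 5
                rows += [(1, "post_night", b, cond, "1", True, post_night)] * 5
        return _trials(rows)

    def test_ten_percent_speedup(self):
        ch = offline_change(self._cohort(pre=400.0, post_nap=360.0, post_night=360.0))
        assert np.allclose(ch["change_pct"], 10.0)

    def test_no_change_is_zero(self):
        ch = offline_change(self._cohort(pre=400.0, post_nap=400.0, post_night=400.0))
        assert np.allclose(ch["change_pct"], 0.0)

    def test_first_pre_test_block_excluded(self):
        df = self._cohort(pre=400.0)
        # corrupt block 1 of pre_test; default pre blocks are 2-4
        df.loc[(df.session == "pre_test") & (df.block == 1), "rt_ms"] = 9999.0
        ch = offline_change(df)
        assert np.allclose(ch["change_pct"], 10.0)

    def test_missing_condition_raises(self):
        df = self._cohort()
        with pytest.raises(ValueError, match="no correct trials"):
            offline_change(df[df.condition == "reactivated"])

    def test_scale_invariance(self):
        df = self._cohort(pre=400.0, post_nap=340.0, post_night=380.0)
        ch1 = offline_change(df)
        df2 = df.copy()
        df2["rt_ms"] *= 3.7
        ch2 = offline_change(df2)
        np.testing.assert_allclose(ch1["change_pct"], ch2["change_pct"])


class TestTMRIndex:
    def _changes(self, r=(10.0, 12.0), nr=(5.0, 7.0), participant=1):
        return pd.DataFrame(
            [
                (participant, "reactivated", "post_nap", r[0]),
                (participant, "reactivated", "post_night", r[1]),
                (participant, "non_reactivated", "post_nap", nr[0]),
                (participant, "non_reactivated", "post_night", nr[1]),
            ],
            columns=["participant", "condition", "time_point", "change_pct"],
        )

    def test_arithmetic(self):
        idx = tmr_index(self._changes())
        assert idx["index_pct"].iloc[0] == pytest.approx(5.0)

    def test_identical_conditions_give_zero(self):
        idx = tmr_index(self._changes(r=(6.0, 8.0), nr=(6.0, 8.0)))
        assert idx["index_pct"].iloc[0] == pytest.approx(0.0)

    def test_missing_cell_raises(self):
        with pytest.raises(ValueError, match="missing"):
            tmr_index(self._changes().iloc[:3])

    @settings(max_examples=25, deadline=None)
    @given(delta=st.floats(-50, 50, allow_nan=False))
    def test_shift_invariance(self, delta):
        # adding the same offset to both conditions leaves the index unchanged
        base = tmr_index(self._changes())["index_pct"].iloc[0]
        ch = self._changes()
        ch["change_pct"] += delta
        assert tmr_index(ch)["index_pct"].iloc[0] == pytest.approx(base)


class TestGenerationAccuracy:
    SEQS = {"reactivated": SEQUENCE_A, "non_reactivated": SEQUENCE_B}

    def _gen(self, keys, cond="reactivated"):
        rows = [
            (1, "pre_nap", cond, 1, pos, k) for pos, k in enumerate(keys)
        ]
        return pd.DataFrame(
            rows,
            columns=["participant", "time_point", "condition", "attempt", "position", "key"],
        )

    def test_perfect_reproduction(self):
        acc = generation_accuracy(self._gen(SEQUENCE_A), self.SEQS)
        assert acc["accuracy_pct"].iloc[0] == 100.0

    def test_other_sequence_scores_zero(self):
        # the two trained sequences share no ordinal position
        acc = generation_accuracy(self._gen(SEQUENCE_B), self.SEQS)
        assert acc["accuracy_pct"].iloc[0] == 0.0

    def test_half_correct(self):
        keys = SEQUENCE_A[:4] + SEQUENCE_B[4:]
        acc = generation_accuracy(self._gen(keys), self.SEQS)
        assert acc["accuracy_pct"].iloc[0] == 50.0

    def test_short_attempt_flagged(self):
        acc = generation_accuracy(self._gen(SEQUENCE_A[:5]), self.SEQS)
        assert acc["length_mismatch"].iloc[0]
        assert acc["accuracy_pct"].iloc[0] == 100.0


class TestOverallChange:
    def _cohort(self, seq_pre=500.0, seq_post=400.0, rand=480.0):
        rows = []
        for b in range(1, 17):
            for cond in ("reactivated", "non_reactivated"):
                rows += [(1, "pre_train", b, cond, "1", True, seq_pre)] * 3
                rows += [(1, "post_night", b, cond, "1", True, seq_post)] * 3
        for b in range(1, 5):
            rows += [(1, "random_pre", b, "random", "1", True, rand)] * 3
            rows += [(1, "random_post", b, "random", "1", True, rand)] * 3
        return _trials(rows)

    def test_arithmetic_and_flat_random(self):
        out = overall_change(self._cohort())
        assert out["sequential_change_pct"].iloc[0] == pytest.approx(20.0)
        assert out["random_change_pct"].iloc[0] == pytest.approx(0.0)

    def test_sequence_learning_exceeds_random_on_synthetic_cohort(self):
        from sleeptmr.simulate import BehaviorSpec, SimulationConfig, simulate_behavior
        from scipy import stats

        cfg = SimulationConfig(
            behavior=BehaviorSpec(n_participants=8, noise_sd_ms=25.0), seed=2
        )
        out = overall_change(simulate_behavior(cfg))
        t, p = stats.ttest_rel(out["sequential_change_pct"], out["random_change_pct"])
        assert out["sequential_change_pct"].mean() > out["random_change_pct"].mean()
        assert p < 0.001


class TestCounterbalance:
    def test_twelve_combinations(self):
        combos = counterbalance_assignments()
        assert len(combos) == 12
        # all distinct, and each sound-role map is a bijection
        seen = {tuple(sorted(c.items())) for c in combos}
        assert len(seen) == 12
        for c in combos:
            assert {c["sound_sequence_A"], c["sound_sequence_B"], c["sound_control"]} == {1, 2, 3}

    def test_requires_three_distinct_sounds(self):
        with pytest.raises(ValueError):
            counterbalance_assignments((1, 1, 2))
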