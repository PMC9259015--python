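import numpy as np
import pytest

from sleeptmr.evoked import (
    EpochSet,
    baseline_correct,
    downsample,
    epoch,
    erp,
    find_deflection_window,
    tfr_hanning,
    tfr_relchange,
)
from sleeptmr.io import EventList, Recording


def _rec(x, fs=100.0):
    x = np.atleast_2d(x)
    return Recording(x, fs=fs, channels=[f"ch{i}" for i in range(x.shape[0])])


def _epochs(data, fs=100.0, t0=-1.0, conditions=None):
    data = np.asarray(data, float)
    times = t0 + np.arange(data.shape[2]) / fs
    conds = (
        np.asarray(conditions, dtype=object)
        if conditions is not None
        else np.array(["all"] * data.shape[0], dtype=object)
    )
    return EpochSet(data=data, times=times, fs=fs, condition=conds)


class TestEpoching:
    def test_index_arithmetic(self):
        rec = _rec(np.arange(2000.0), fs=100.0)
        ev = EventList([10.0], ["associated"])
        ep = epoch(rec, ev, window=(-1.0, 3.0))
        assert ep.data.shape == (1, 1, 400)
        # epoch starts at sample 900
        assert ep.data[0, 0, 0] == 900.0

    def test_partial_window_dropped_with_warning(self):
        rec = _rec(np.zeros(2000), fs=100.0)
        ev = EventList([0.5, 10.0], ["associated", "associated"])
        with pytest.warns(UserWarning, match="dropped 1"):
            ep = epoch(rec, ev, window=(-1.0, 3.0))
        assert ep.n_trials == 1

    def test_all_dropped_raises(self):
        rec = _rec(np.zeros(200), fs=100.0)
        with pytest.raises(ValueError, match="no events"), pytest.warns(UserWarning):
            epoch(rec, EventList([0.1], ["associated"]), window=(-1.0, 3.0))

    def test_trial_count_matches_kept_cues(self, study_recording):
        cfg, rec, hyp, events, truth, mask = study_recording
        small = downsample(rec, 100.0)
        ep = epoch(small, events, window=(-1.0, 3.0))
        full_margin = (events.onset_s >= 1.0) & (
            events.onset_s + 3.0 <= rec.duration
        )
        assert ep.n_trials == int((events.kept & full_margin).sum())


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        ep = _epochs(np.full((3, 2, 400), 5.0))
        out = baseline_correct(ep)
        assert np.allclose(out.data, 0.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 2, 400))
        a = baseline_correct(_epochs(data))
        b = baseline_correct(_epochs(data + 7.0))
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(1)
        ep = _epochs(rng.standard_normal((5, 3, 400)))
        out = baseline_correct(ep)
        sel = (out.times >= -0.3) & (out.times < -0.1)
        assert np.abs(out.data[:, :, sel].mean(axis=2)).max() < 1e-10

    def test_baseline_outside_epoch_rejected(self):
        ep = _epochs(np.zeros((1, 1, 100)), t0=0.0)
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(ep, base=(-0.3, -0.1))


class TestERP:
    def test_single_trial_identity(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((1, 2, 100))
        waves, counts = erp(_epochs(data), average_channels=False)
        np.testing.assert_allclose(waves["all"], data[0])
        assert counts["all"] == 1

    def test_noise_averages_toward_template(self):
        rng = np.random.default_rng(3)
        t = np.linspace(-1, 3, 400)
        template = -5.0 * np.exp(-0.5 * ((t - 0.5) / 0.1) ** 2)
        data = template[None, None, :] + rng.standard_normal((200, 1, 400))
        waves, _ = erp(_epochs(data))
        # law of large numbers: error ~ sigma/sqrt(n)
        assert np.abs(waves["all"] - template).max() < 5 / np.sqrt(200)

    def test_channel_average_commutes(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((10, 4, 50))
        per_channel, _ = erp(_epochs(data), average_channels=False)
        averaged, _ = erp(_epochs(data), average_channels=True)
        np.testing.assert_allclose(per_channel["all"].mean(axis=0), averaged["all"])

    def test_condition_scaling_linearity(self):
        t = np.linspace(-1, 3, 400)
        template = np.sin(2 * np.pi * t)
        data = np.stack([template[None, :], 2 * template[None, :]])
        waves, _ = erp(_epochs(data, conditions=["a", "b"]))
        np.testing.assert_allclose(waves["b"], 2 * waves["a"])


class TestDeflectionWindow:
    def test_recovers_trough_location(self):
        rng = np.random.default_rng(5)
        fs = 100.0
        t = np.arange(-100, 300) / fs
        template = -4.0 * np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2)
        erps = template[None, :] + 0.8 * rng.standard_normal((20, len(t)))
        windows = find_deflection_window(erps, t)
        neg = [w for w in windows if w[2] < 0]
        assert neg
        lo, hi, _ = neg[0]
        assert lo < 0.5 < hi
        assert lo > 0.3 and hi < 0.8

    def test_pure_noise_rarely_significant(self):
        from sleeptmr.cluster import PermutationConfig

        hits = 0
        n_sim = 30
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            erps = rng.standard_normal((16, 100))
            t = np.linspace(-0.5, 1.5, 100)
            cfg = PermutationConfig(n_perm=200, seed=s)
            if find_deflection_window(erps, t, cfg):
                hits += 1
        assert hits <= 4  # ~5% family-wise error


class TestTFR:
    def test_window_length_five_cycles(self):
        # at 10 Hz the adaptive window is 0.5 s: NaN support reflects it
        ep = _epochs(np.random.default_rng(0).standard_normal((1, 1, 400)))
        tfr = tfr_hanning(ep, freqs=[10.0])
        valid = ~np.isnan(tfr.data[0, 0, 0])
        # first valid center >= 0.25 s after epoch start
        first = tfr.times[valid][0]
        assert first - ep.times[0] == pytest.approx(0.25, abs=0.03)

    def test_pure_sinusoid_flat_power(self):
        fs = 100.0
        t = np.arange(-100, 300) / fs
        ep = _epochs(np.sin(2 * np.pi * 10.0 * t)[None, None, :])
        tfr = tfr_hanning(ep, freqs=[10.0])
        row = tfr.data[0, 0, 0]
        core = row[~np.isnan(row)]
        assert np.nanstd(core) / np.nanmean(core) < 0.05
        # amplitude-normalized power of a unit sinusoid is ~1
        assert np.nanmean(core) == pytest.approx(1.0, abs=0.1)

    def test_quadratic_amplitude_scaling(self):
        fs = 100.0
        t = np.arange(-100, 300) / fs
        x = np.sin(2 * np.pi * 13.0 * t)
        t1 = tfr_hanning(_epochs(x[None, None, :]), freqs=[13.0])
        t2 = tfr_hanning(_epochs(2 * x[None, None, :]), freqs=[13.0])
        ratio = np.nanmean(t2.data) / np.nanmean(t1.data)
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_too_short_epoch_rejected(self):
        ep = _epochs(np.zeros((1, 1, 50)))
        with pytest.raises(ValueError, match="epoch shorter"):
            tfr_hanning(ep, freqs=[5.0])

    def test_relchange_near_zero_for_stationary(self):
        fs = 100.0
        t = np.arange(-100, 300) / fs
        x = np.sin(2 * np.pi * 12.0 * t)
        tfr = tfr_hanning(_epochs(x[None, None, :]), freqs=[12.0])
        rel = tfr_relchange(tfr)
        assert np.nanmax(np.abs(rel.data)) < 0.05

    def test_relchange_detects_power_doubling(self):
        fs = 100.0
        t = np.arange(-100, 300) / fs
        x = np.sin(2 * np.pi * 12.0 * t).copy()
        burst = (t >= 1.0) & (t < 2.0)
        x[burst] *= np.sqrt(2.0)  # power x2 in the burst
        tfr = tfr_hanning(_epochs(x[None, None, :]), freqs=[12.0])
        rel = tfr_relchange(tfr)
        mid = (rel.times >= 1.3) & (rel.times < 1.7)
        assert np.nanmean(rel.data[0, 0, 0, mid]) == pytest.approx(1.0, abs=0.15)
        assert np.nanmin(rel.data) >= -1.0

    def test_evoked_trough_recovered_end_to_end(self, study_recording):
        cfg, rec, hyp, events, truth, mask = study_recording
        small = downsample(rec, 100.0)
        ep = baseline_correct(epoch(small, events, window=(-1.0, 3.0)))
        waves, counts = erp(ep)
        assoc = waves["associated"]
        sel = (ep.times > 0.3) & (ep.times < 0.7)
        trough_t = ep.times[sel][np.argmin(assoc[sel])]
        assert trough_t == pytest.approx(cfg.stim.evoked_latency_s, abs=0.1)
        # deeper configured template -> more negative measured trough
        depth = {c: waves[c][sel].min() for c in ("associated", "unassociated")}
        assert depth["associated"] < depth["unassociated"]
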