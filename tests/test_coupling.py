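import numpy as np
import pytest

from sleeptmr.coupling import (
    PhaseAmplitudeEpochs,
    erpac,
    erpac_from_arrays,
    extract_phase_amplitude,
    phase_amplitude_from_trials,
    preferred_phase,
    rayleigh_test,
    watson_williams,
)
from sleeptmr.io import Recording
from sleeptmr.simulate import simulate_coupled_trials


def _pae(phase, amplitude, freqs=None, times=None):
    n_t = phase.shape[1]
    return PhaseAmplitudeEpochs(
        phase=phase,
        amplitude=amplitude,
        times=times if times is not None else np.arange(n_t) / 100.0,
        freqs=np.asarray(freqs if freqs is not None else [13.0]),
        condition=np.array(["all"] * phase.shape[0], dtype=object),
    )


class TestExtraction:
    def test_cosine_phase_convention(self):
        # phase 0 at the positive peak of a 1 Hz cosine, +/-pi at the trough
        fs = 100.0
        t = np.arange(int(60 * fs)) / fs
        rec = Recording(
            (50 * np.cos(2 * np.pi * 1.0 * t))[None, :], fs=fs, channels=["Cz"]
        )
        pae = extract_phase_amplitude(
            rec, event_times_s=np.arange(10, 45, 1.0), window=(-0.5, 0.5)
        )
        # peaks of the cosine sit at integer seconds = epoch centres
        mid = np.argmin(np.abs(pae.times))
        assert np.abs(pae.phase[:, mid]).max() < 0.15
        trough = np.argmin(np.abs(pae.times + 0.5))
        assert np.abs(np.abs(pae.phase[:, trough]) - np.pi).max() < 0.15

    def test_phase_range(self):
        ep, times, _ = simulate_coupled_trials(n_trials=40, window=(-6, 7), seed=0)
        pae = phase_amplitude_from_trials(ep, times, 100.0, crop=(-1, 2))
        assert pae.phase.max() <= np.pi + 1e-9
        assert pae.phase.min() >= -np.pi - 1e-9
        assert (pae.amplitude >= 0).all()

    def test_burst_band_localization(self):
        fs = 100.0
        t = np.arange(int(60 * fs)) / fs
        x = np.random.default_rng(0).standard_normal(len(t))
        burst = (t >= 30) & (t < 31)
        x[burst] += 20 * np.cos(2 * np.pi * 13.0 * t[burst])
        rec = Recording(x[None, :], fs=fs, channels=["Cz"])
        pae = extract_phase_amplitude(
            rec, event_times_s=np.array([30.5]), window=(-0.5, 0.5), min_trials=1
        )
        prof = pae.amplitude[0].mean(axis=1)  # freq profile during the burst
        assert pae.freqs[np.argmax(prof)] == pytest.approx(13.0, abs=1.0)


class TestERPAC:
    def test_constant_amplitude_gives_zero(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, (50, 10))
        amp = np.ones((50, 1, 10))
        rho = erpac(_pae(phase, amp)).rho
        assert np.allclose(rho, 0.0)

    def test_perfect_coupling_approaches_one(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(-np.pi, np.pi, (500, 5))
        amp = np.cos(phase - 1.0)[:, None, :] + 2.0
        rho = erpac(_pae(phase, amp)).rho
        assert rho.min() > 0.97

    def test_matches_independent_circular_linear_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        phase = rng.uniform(-np.pi, np.pi, (80, 4))
        amp = rng.gamma(2.0, 1.0, (80, 1, 4)) + 0.3 * np.cos(phase)[:, None, :]
        rho = erpac_from_arrays(phase[:, None, :], amp)
        for k in range(4):
            expected = pingouin.circ_corrcl(phase[:, k], amp[:, 0, k])[0]
            assert rho[0, k] == pytest.approx(expected, abs=1e-10)

    def test_amplitude_offset_invariance(self):
        rng = np.random.default_rng(3)
        phase = rng.uniform(-np.pi, np.pi, (60, 3))
        amp = rng.gamma(2.0, 1.0, (60, 1, 3))
        r1 = erpac_from_arrays(phase[:, None, :], amp)
        r2 = erpac_from_arrays(phase[:, None, :], amp + 100.0)
        np.testing.assert_allclose(r1, r2, atol=1e-10)

    def test_too_few_trials_rejected(self):
        rng = np.random.default_rng(4)
        pae = _pae(rng.uniform(-1, 1, (10, 5)), rng.random((10, 1, 5)))
        with pytest.raises(ValueError, match="trials"):
            erpac(pae)

    def test_recovers_injected_band_phase_and_window(self):
        ep, times, _ = simulate_coupled_trials(
            n_trials=250,
            depth=0.8,
            carrier_hz=14.0,
            preferred_phase_rad=-np.pi / 2,
            window=(-6, 7),
            coupling_window=(0.0, 1.5),
            seed=12,
        )
        pae = phase_amplitude_from_trials(ep, times, 100.0, crop=(-1, 2.5))
        m = erpac(pae)
        band = (pae.freqs >= 12) & (pae.freqs <= 16)
        inside = (m.times >= 0.3) & (m.times < 1.2)
        outside = m.times < -0.4
        off_band = (pae.freqs < 9) | (pae.freqs > 20)
        assert m.rho[band][:, inside].mean() > 0.6
        # coupling confined to the injected band and window
        assert m.rho[off_band][:, inside].mean() < 0.25
        assert m.rho[band][:, outside].mean() < 0.25


class TestPreferredPhase:
    def test_recovery_within_one_bin(self):
        ep, times, _ = simulate_coupled_trials(
            n_trials=300, depth=0.8, preferred_phase_rad=-np.pi / 2, window=(-6, 7), seed=5
        )
        pae = phase_amplitude_from_trials(ep, times, 100.0, crop=(-1, 2))
        pp = preferred_phase(pae, band_hz=(12, 16), n_bins=18)
        bin_width = 2 * np.pi / 18
        err = np.angle(np.exp(1j * (pp.pp_rad - (-np.pi / 2))))
        assert abs(err) <= bin_width

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        phase = rng.uniform(-np.pi, np.pi, (100, 20))
        amp = (2 + np.cos(phase - 0.7))[:, None, :]
        p1 = preferred_phase(_pae(phase, amp))
        p2 = preferred_phase(_pae(phase, 2 * amp))
        assert p1.pp_rad == p2.pp_rad

    def test_uniform_amplitude_flagged_by_rayleigh(self):
        rng = np.random.default_rng(7)
        phase = rng.uniform(-np.pi, np.pi, 2000)
        _, _, p = rayleigh_test(phase)
        assert p > 0.01  # no evidence of concentration


class TestRayleigh:
    def test_degenerate_concentration(self):
        n = 50
        R, z, p = rayleigh_test(np.full(n, 1.2))
        assert R == pytest.approx(1.0)
        assert p == pytest.approx(np.exp(-n) * (1 + (2 * n - n**2) / (4 * n)), rel=1e-6)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        phases = rng.vonmises(0.5, 2.0, 100)
        R1, _, _ = rayleigh_test(phases)
        R2, _, _ = rayleigh_test(np.angle(np.exp(1j * (phases + 1.0))))
        assert R1 == pytest.approx(R2, abs=1e-12)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            _, _, p = rayleigh_test(rng.uniform(-np.pi, np.pi, 1000))
            ps.append(p)
        ps = np.asarray(ps)
        assert 0.4 < ps.mean() < 0.6
        assert 0.01 <= np.mean(ps < 0.05) <= 0.10 or np.mean(ps < 0.05) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            rayleigh_test(np.zeros(5))


class TestWatsonWilliams:
    def test_null_calibration(self):
        rng = np.random.default_rng(10)
        ps = [
            watson_williams(rng.vonmises(0.5, 5.0, 40), rng.vonmises(0.5, 5.0, 40))[1]
            for _ in range(200)
        ]
        ps = np.asarray(ps)
        assert 0.4 < ps.mean() < 0.6
        assert np.mean(ps < 0.05) < 0.12

    def test_power_for_opposite_means(self):
        rng = np.random.default_rng(11)
        hits = sum(
            watson_williams(rng.vonmises(0.0, 5.0, 50), rng.vonmises(np.pi, 5.0, 50))[1]
            < 0.001
            for _ in range(100)
        )
        assert hits >= 99

    def test_label_permutation_symmetry(self):
        rng = np.random.default_rng(12)
        a = rng.vonmises(0.3, 5.0, 30)
        b = rng.vonmises(0.3, 5.0, 30)
        F1, _ = watson_williams(a, b)
        F2, _ = watson_williams(b, a)
        assert F1 == pytest.approx(F2, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 5"):
            watson_williams(np.zeros(3), np.zeros(30))

    def test_low_concentration_warns(self):
        rng = np.random.default_rng(13)
        with pytest.warns(UserWarning, match="0.45"):
            watson_williams(
                rng.uniform(-np.pi, np.pi, 50), rng.uniform(-np.pi, np.pi, 50)
            )
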