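"""Synthetic polysomnography and SRTT behavior with known ground truth.

Every downstream stage of the pipeline (event detection, evoked analyses,
SO-sigma coupling, behavioral indices) is exercised against recordings and
trial tables generated here, so recovery of the configured parameters is a
testable property rather than an article of faith.

What is emulated
----------------
* NREM2-3 background EEG as band-limited 1/f Gaussian noise.
* Slow waves as asymmetric half-sine pairs (negative then positive
  half-wave) with controlled peak-to-peak amplitude and durations, placed
  by a Poisson process with overlap rejection.
* Sleep spindles as Hann-enveloped sigma-band bursts with controlled
  duration, amplitude and centre frequency.
* SO-phase -> sigma-amplitude coupling: a slow oscillation plus a sigma
  carrier whose envelope is ``1 + depth*cos(phi_SO - preferred_phase)``.
* The auditory stimulation protocol: 3-min blocks of one cue type at 5-s
  ISI alternating with 1-min silent rest, restricted to NREM2-3, with a
  negative evoked deflection added after each cue.
* SRTT reaction-time series: exponential learning to a plateau, block
  structure (64 presses, two 8-element sequences), condition-specific
  offline gains at the post-nap/post-night retests, i.i.d. trial noise and
  injected outliers.

What is *not* emulated: real sleep microstructure (stage dynamics are a
user-given script), artifacts, electrode topography (channels share the
embedded events with independent noise), and acoustic waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .io import EventList, Hypnogram, IntervalSet, Recording

__all__ = [
    "SWSpec",
    "SpindleSpec",
    "CouplingSpec",
    "StimSpec",
    "BehaviorSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_recording",
    "simulate_behavior",
    "simulate_coupled_trials",
    "SEQUENCE_A",
    "SEQUENCE_B",
]

# the two eight-element finger sequences of the bimanual SRTT
SEQUENCE_A = "16354827"
SEQUENCE_B = "72645183"


@dataclass
class SWSpec:
    """Embedded slow-wave population."""

    rate_per_min: float = 5.0
    ptp_uv: tuple[float, float] = (100.0, 150.0)
    # the positive half-wave duration is drawn as pos_ratio x the negative
    # duration: near-balanced lobes keep the band-passed wave's half-wave
    # durations inside the detection bounds (a strongly asymmetric pair
    # smears its positive lobe past 1 s once the 0.3-2 Hz filter removes
    # the DC content)
    neg_dur_s: tuple[float, float] = (0.45, 0.9)
    pos_ratio: tuple[float, float] = (0.85, 1.05)
    neg_frac: float = 0.55  # share of PTP carried by the negative half-wave


@dataclass
class SpindleSpec:
    rate_per_min: float = 2.0
    freq_hz: float = 13.0
    dur_s: tuple[float, float] = (0.7, 1.4)
    amplitude_uv: float = 30.0  # envelope peak; sigma-band PTP = 2x


@dataclass
class CouplingSpec:
    """Continuous SO + phase-locked sigma carrier (depth 0 disables)."""

    depth: float = 0.0
    preferred_phase_rad: float = -np.pi / 2
    carrier_hz: float = 14.0
    so_freq_hz: float = 0.75
    so_amplitude_uv: float = 20.0
    sigma_amplitude_uv: float = 5.0


@dataclass
class StimSpec:
    block_s: float = 180.0
    rest_s: float = 60.0
    isi_s: float = 5.0
    conditions: tuple[str, str] = ("associated", "unassociated")
    evoked_uv: dict = field(
        default_factory=lambda: {"associated": -30.0, "unassociated": -20.0}
    )
    evoked_latency_s: float = 0.5
    evoked_width_s: float = 0.12  # Gaussian sigma of the trough


@dataclass
class BehaviorSpec:
    n_participants: int = 24
    baseline_rt_ms: float = 500.0
    plateau_rt_ms: float = 380.0
    learning_tau_blocks: float = 4.0
    offline_gain_pct: dict = field(
        default_factory=lambda: {"reactivated": 10.0, "non_reactivated": 5.0}
    )
    random_rt_ms: float = 480.0
    noise_sd_ms: float = 40.0
    outlier_rate: float = 0.0
    error_rate: float = 0.03


@dataclass
class SimulationConfig:
    fs: float = 500.0
    stage_script: tuple = (("W", 2.0), ("N2", 20.0), ("N3", 10.0))
    background_rms_uv: float = 12.0
    background_alpha: float = 1.0
    sw: SWSpec = field(default_factory=SWSpec)
    spindle: SpindleSpec = field(default_factory=SpindleSpec)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    stim: StimSpec = field(default_factory=StimSpec)
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    channels: tuple = ("Fz", "C3", "Cz", "C4", "Pz", "Oz")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling.depth <= 1.0:
            raise ValueError("coupling depth must be in [0, 1]")
        if self.sw.rate_per_min < 0 or self.spindle.rate_per_min < 0:
            raise ValueError("event rates must be non-negative")


@dataclass
class GroundTruth:
    """Realized draws of everything the simulator embedded."""

    sw: pd.DataFrame  # neg_peak_s, start_s, end_s, ptp_uv, neg_amp_uv, pos_amp_uv
    spindles: pd.DataFrame  # start_s, end_s, freq_hz, amplitude_uv
    coupling: dict  # preferred_phase_rad, depth, carrier_hz
    evoked: dict  # condition -> (times, template) of the added deflection
    offline_gain_pct: dict


def _pink_noise(rng, n, fs, alpha, band=(0.1, 45.0)):
    """Band-limited Gaussian 1/f^alpha noise, unit RMS."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    with np.errstate(divide="ignore"):
        scale = np.where(freqs > 0, freqs ** (-alpha / 2.0), 0.0)
    scale[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _sw_waveform(neg_dur, pos_dur, neg_amp, pos_amp, fs, rebound_frac=0.3):
    """Negative then positive half-sine, with a small trailing negative
    rebound (slow oscillations come in trains; the rebound also gives the
    positive half-wave a crisp terminal zero-crossing after band-passing
    instead of a near-zero plateau)."""
    n_neg = max(int(round(neg_dur * fs)), 2)
    n_pos = max(int(round(pos_dur * fs)), 2)
    w = np.concatenate(
        [
            -neg_amp * np.sin(np.pi * np.arange(n_neg) / n_neg),
            pos_amp * np.sin(np.pi * np.arange(n_pos) / n_pos),
            -rebound_frac * pos_amp * np.sin(np.pi * np.arange(n_pos) / n_pos),
        ]
    )
    return w


def _template_meets_thresholds(wf: np.ndarray, fs: float) -> bool:
    """Check the isolated band-passed template against the five logical
    slow-wave detection thresholds (durations from zero-crossings,
    amplitude and PTP bounds)."""
    ni = int(np.argmin(wf))
    pj = ni + int(np.argmax(wf[ni:]))
    neg_amp, pos_amp = -wf[ni], wf[pj]
    sign = np.signbit(wf)
    zc = np.flatnonzero(sign[1:] != sign[:-1])
    before = zc[zc < ni]
    between = zc[(zc >= ni) & (zc < pj)]
    after = zc[zc >= pj]
    if not (before.size and between.size and after.size):
        return False
    neg_dur = (between[0] - before[-1]) / fs
    pos_dur = (after[0] - between[0]) / fs
    return (
        0.3 <= neg_dur <= 1.5
        and 0.1 <= pos_dur <= 1.0
        and 40 <= neg_amp <= 300
        and 10 <= pos_amp <= 200
        and 75 <= neg_amp + pos_amp <= 500
    )


def _place_events(rng, rate_per_min, dur_draw, allowed, fs, margin_s=0.5):
    """Poisson placement inside the allowed mask, rejecting overlaps.

    Returns list of (start_sample, n_samples). ``dur_draw(rng)`` yields the
    event duration in seconds.
    """
    n = len(allowed)
    total_min = allowed.sum() / fs / 60.0
    n_events = rng.poisson(rate_per_min * total_min)
    occupied = np.zeros(n, dtype=bool)
    placed = []
    attempts = 0
    allowed_idx = np.flatnonzero(allowed)
    if allowed_idx.size == 0 or n_events == 0:
        return placed
    while len(placed) < n_events and attempts < 50 * n_events:
        attempts += 1
        dur = dur_draw(rng)
        n_samp = int(round(dur * fs))
        start = int(rng.choice(allowed_idx))
        stop = start + n_samp
        m = int(margin_s * fs)
        if stop >= n:
            continue
        lo, hi = max(start - m, 0), min(stop + m, n)
        if not allowed[start:stop].all() or occupied[lo:hi].any():
            continue
        occupied[lo:hi] = True
        placed.append((start, n_samp))
    return sorted(placed)


def simulate_recording(
    cfg: SimulationConfig,
) -> tuple[Recording, Hypnogram, EventList, GroundTruth]:
    """Generate a multichannel nap recording with full ground truth.

    The same seed yields a bit-identical output (NumPy PCG64 generator).
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    stages = []
    for stage, minutes in cfg.stage_script:
        stages.extend([stage] * int(round(minutes * 2)))  # 30-s epochs
    hyp = Hypnogram(stages)
    n = int(round(hyp.duration * fs))
    t = np.arange(n) / fs

    nrem = np.zeros(n, dtype=bool)
    ep_samp = int(round(30 * fs))
    for i, st in enumerate(hyp.stages):
        if st in ("N2", "N3"):
            nrem[i * ep_samp : (i + 1) * ep_samp] = True

    n_ch = len(cfg.channels)
    signal = np.empty((n_ch, n))
    for c in range(n_ch):
        signal[c] = cfg.background_rms_uv * _pink_noise(
            rng, n, fs, cfg.background_alpha
        )

    common = np.zeros(n)  # events shared across channels

    # --- slow waves -------------------------------------------------------
    # The configured PTP is defined on the detection-filtered (0.3-2 Hz)
    # trace, matching how the detection thresholds are applied: each raw
    # template is rescaled so its band-passed peak-to-peak equals the draw.
    from scipy.signal import fftconvolve

    from .filters import design_bandpass

    sw = cfg.sw
    sw_rows = []
    sw_taps = design_bandpass(fs, 0.3, 2.0, trans=0.2).taps
    max_dur = sw.neg_dur_s[1] * (1 + sw.pos_ratio[1])
    slots = _place_events(
        rng, sw.rate_per_min, lambda r: max_dur, nrem, fs, margin_s=0.5
    )
    for start, _ in slots:
        neg_dur = rng.uniform(*sw.neg_dur_s)
        pos_dur = neg_dur * rng.uniform(*sw.pos_ratio)
        ptp = rng.uniform(*sw.ptp_uv)
        neg_amp = sw.neg_frac * ptp
        pos_amp = ptp - neg_amp
        w = _sw_waveform(neg_dur, pos_dur, neg_amp, pos_amp, fs)
        # measure the isolated template through the detection band-pass and
        # rescale so the configured PTP holds on the filtered trace
        pad = np.zeros(len(sw_taps) // 2)
        wf = fftconvolve(np.r_[pad, w, pad], sw_taps, mode="same")
        ptp_f = wf.max() - wf.min()
        if ptp_f <= 0:
            continue
        scale = ptp / ptp_f
        w *= scale
        wf *= scale
        stop = start + len(w)
        if stop > n:
            continue
        common[start:stop] += w
        n_neg = max(int(round(neg_dur * fs)), 2)
        sw_rows.append(
            {
                "start_s": start / fs,
                "neg_peak_s": (start + n_neg // 2) / fs,
                "end_s": stop / fs,
                "neg_amp_uv": float(-wf.min()),
                "pos_amp_uv": float(wf.max()),
                "ptp_uv": ptp,
                "meets_thresholds": _template_meets_thresholds(wf, fs),
            }
        )
    sw_truth = pd.DataFrame(
        sw_rows,
        columns=[
            "start_s",
            "neg_peak_s",
            "end_s",
            "neg_amp_uv",
            "pos_amp_uv",
            "ptp_uv",
            "meets_thresholds",
        ],
    )

    # --- spindles ---------------------------------------------------------
    sp = cfg.spindle
    sp_rows = []
    slots = _place_events(
        rng,
        sp.rate_per_min,
        lambda r: r.uniform(*sp.dur_s),
        nrem & (common == 0),
        fs,
        margin_s=0.5,
    )
    for start, n_samp in slots:
        dur = n_samp / fs
        env = sp.amplitude_uv * np.hanning(n_samp)
        phase0 = rng.uniform(0, 2 * np.pi)
        burst = env * np.cos(2 * np.pi * sp.freq_hz * np.arange(n_samp) / fs + phase0)
        common[start : start + n_samp] += burst
        sp_rows.append(
            {
                "start_s": start / fs,
                "end_s": (start + n_samp) / fs,
                "duration_s": dur,
                "freq_hz": sp.freq_hz,
                "amplitude_uv": sp.amplitude_uv,
            }
        )
    sp_truth = pd.DataFrame(
        sp_rows,
        columns=["start_s", "end_s", "duration_s", "freq_hz", "amplitude_uv"],
    )

    # --- SO-sigma coupling (controlled injection; depth 0 disables) -------
    cp = cfg.coupling
    if cp.depth > 0 and cp.so_amplitude_uv > 0:
        so_phase0 = rng.uniform(0, 2 * np.pi)
        so_phase = 2 * np.pi * cp.so_freq_hz * t + so_phase0
        so_wave = cp.so_amplitude_uv * np.cos(so_phase)
        common += np.where(nrem, so_wave, 0.0)
        env = cp.sigma_amplitude_uv * (
            1.0 + cp.depth * np.cos(so_phase - cp.preferred_phase_rad)
        )
        carrier_phase0 = rng.uniform(0, 2 * np.pi)
        sigma = env * np.cos(2 * np.pi * cp.carrier_hz * t + carrier_phase0)
        common += np.where(nrem, sigma, 0.0)

    # --- auditory cue schedule (Fig-style blocked design) -----------------
    st = cfg.stim
    onsets, conds = [], []
    block_start = 0.0
    k = 0
    while block_start + st.isi_s < hyp.duration:
        cond = st.conditions[k % len(st.conditions)]
        t_cue = block_start
        while t_cue < block_start + st.block_s - 1e-9:
            idx = int(t_cue * fs)
            if idx < n and nrem[idx]:  # manual stop outside NREM2-3
                onsets.append(t_cue)
                conds.append(cond)
            t_cue += st.isi_s
        block_start += st.block_s + st.rest_s
        k += 1

    # evoked deflection: negative Gaussian trough after each cue
    ev_times = np.arange(0, int(2.0 * fs)) / fs
    templates = {}
    for cond in st.conditions:
        templates[cond] = st.evoked_uv.get(cond, 0.0) * np.exp(
            -0.5 * ((ev_times - st.evoked_latency_s) / st.evoked_width_s) ** 2
        )
    for onset, cond in zip(onsets, conds):
        i0 = int(round(onset * fs))
        i1 = min(i0 + len(ev_times), n)
        common[i0:i1] += templates[cond][: i1 - i0]

    signal += common[None, :]
    rec = Recording(signal=signal, fs=fs, channels=list(cfg.channels))
    events = EventList(np.array(onsets), np.array(conds, dtype=object))
    truth = GroundTruth(
        sw=sw_truth,
        spindles=sp_truth,
        coupling={
            "preferred_phase_rad": cp.preferred_phase_rad,
            "depth": cp.depth,
            "carrier_hz": cp.carrier_hz,
        },
        evoked={c: (ev_times, templates[c]) for c in st.conditions},
        offline_gain_pct=dict(cfg.behavior.offline_gain_pct),
    )
    return rec, hyp, events, truth


# ---------------------------------------------------------------------------
# trial-level coupling generator
# ---------------------------------------------------------------------------

def simulate_coupled_trials(
    n_trials: int = 300,
    depth: float = 0.8,
    preferred_phase_rad: float = -np.pi / 2,
    carrier_hz: float = 14.0,
    so_freq_hz: float = 0.75,
    window: tuple[float, float] = (-1.0, 2.0),
    coupling_window: tuple[float, float] | None = None,
    fs: float = 100.0,
    so_amplitude_uv: float = 75.0,
    sigma_amplitude_uv: float = 10.0,
    noise_rms_uv: float = 5.0,
    seed: int = 0,
):
    """Epochs with a controlled SO-phase -> sigma-amplitude relationship.

    Each trial is a slow oscillation with a random initial phase plus a
    sigma carrier whose envelope is ``1 + depth*cos(phi_SO - pp)``; across
    trials the SO phase at any fixed time is uniform, which is exactly the
    regime the event-related coupling estimator assumes.  When
    ``coupling_window`` is given the envelope modulation is confined to
    that time range (flat envelope outside), so the recovered coupling
    should be confined there too.

    Returns ``(epochs, times, true_phase)`` where ``epochs`` is
    (n_trials, n_times) in µV and ``true_phase`` the per-trial SO phase
    track (cosine convention: 0 at SO peak).
    """
    rng = np.random.default_rng(seed)
    times = np.arange(round(window[0] * fs), round(window[1] * fs)) / fs
    phi0 = rng.uniform(-np.pi, np.pi, n_trials)
    so_phase = 2 * np.pi * so_freq_hz * times[None, :] + phi0[:, None]
    so_phase = np.angle(np.exp(1j * so_phase))
    so = so_amplitude_uv * np.cos(so_phase)
    mod = depth * np.cos(so_phase - preferred_phase_rad)
    if coupling_window is not None:
        in_win = (times >= coupling_window[0]) & (times < coupling_window[1])
        mod = mod * in_win[None, :]
    env = sigma_amplitude_uv * (1 + mod)
    carrier = np.cos(
        2 * np.pi * carrier_hz * times[None, :]
        + rng.uniform(0, 2 * np.pi, n_trials)[:, None]
    )
    noise = noise_rms_uv * rng.standard_normal((n_trials, len(times)))
    return so + env * carrier + noise, times, so_phase


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

# (session, n_blocks, kind) in chronological order
_SESSIONS = (
    ("random_pre", 4, "random"),
    ("pre_train", 16, "sequence"),
    ("pre_test", 4, "sequence"),
    ("post_nap", 4, "sequence"),
    ("post_night", 16, "sequence"),
    ("random_post", 4, "random"),
)


def simulate_behavior(cfg: SimulationConfig) -> pd.DataFrame:
    """SRTT trial table for a synthetic cohort.

    Columns: participant, session, block, condition, key, correct, rt_ms.
    Sequential blocks hold 64 presses (two sequences x 4 repetitions x 8
    elements); the learning curve applies during pre-nap training, the
    pre-nap test sits at the plateau, and the post-nap / post-night
    sessions start at the plateau reduced by the configured
    condition-specific offline gain.
    """
    b = cfg.behavior
    for v in (b.baseline_rt_ms, b.plateau_rt_ms, b.noise_sd_ms):
        if v < 0:
            raise ValueError("RT parameters must be non-negative")
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    seq_keys = {"reactivated": SEQUENCE_A, "non_reactivated": SEQUENCE_B}
    gains = b.offline_gain_pct
    for p in range(1, b.n_participants + 1):
        for session, n_blocks, kind in _SESSIONS:
            for block in range(1, n_blocks + 1):
                if kind == "random":
                    mean_rt = {None: b.random_rt_ms}
                    conds = [None]
                else:
                    conds = ["reactivated", "non_reactivated"]
                    mean_rt = {}
                    for cond in conds:
                        if session == "pre_train":
                            m = b.plateau_rt_ms + (
                                b.baseline_rt_ms - b.plateau_rt_ms
                            ) * np.exp(-(block - 1) / b.learning_tau_blocks)
                        elif session == "pre_test":
                            m = b.plateau_rt_ms
                        else:  # post_nap / post_night: plateau minus gain
                            m = b.plateau_rt_ms * (1 - gains.get(cond, 0.0) / 100.0)
                        mean_rt[cond] = m
                for cond in conds:
                    n_press = 64 if kind == "random" else 32
                    seq = seq_keys.get(cond, "00000000")
                    for i in range(n_press):
                        rt = mean_rt[cond] + (
                            b.noise_sd_ms * rng.standard_normal()
                            if b.noise_sd_ms > 0
                            else 0.0
                        )
                        if b.outlier_rate > 0 and rng.random() < b.outlier_rate:
                            rt += rng.choice([-1, 1]) * rng.uniform(4, 8) * max(
                                b.noise_sd_ms, 1.0
                            )
                        correct = rng.random() >= b.error_rate
                        key = (
                            seq[i % 8]
                            if kind == "sequence"
                            else str(rng.integers(1, 9))
                        )
                        rows.append(
                            (
                                p,
                                session,
                                block,
                                cond if cond is not None else "random",
                                key,
                                bool(correct),
                                max(rt, 50.0),
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=["participant", "session", "block", "condition", "key", "correct", "rt_ms"],
    )


def simulate_generation(
    cfg: SimulationConfig, accuracy: dict | None = None
) -> pd.DataFrame:
    """Generation-task presses: 4 attempts per cued sequence per time point.

    ``accuracy`` maps condition to the per-position probability of pressing
    the key the cued sequence prescribes (default 0.8 / 0.6).
    """
    accuracy = accuracy or {"reactivated": 0.8, "non_reactivated": 0.6}
    rng = np.random.default_rng(cfg.seed + 2)
    seq_keys = {"reactivated": SEQUENCE_A, "non_reactivated": SEQUENCE_B}
    rows = []
    for p in range(1, cfg.behavior.n_participants + 1):
        for time_point in ("pre_nap", "post_night"):
            for cond, seq in seq_keys.items():
                for attempt in range(1, 5):
                    for pos, true_key in enumerate(seq):
                        if rng.random() < accuracy[cond]:
                            key = true_key
                        else:
                            others = [k for k in "12345678" if k != true_key]
                            key = others[rng.integers(0, 7)]
                        rows.append((p, time_point, cond, attempt, pos, key))
    return pd.DataFrame(
        rows,
        columns=["participant", "time_point", "condition", "attempt", "position", "key"],
    )
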