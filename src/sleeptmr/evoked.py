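"""Cue-locked epoching, ERPs, trough-window identification, and TFRs.

Event-related analyses run on data down-sampled to 100 Hz.  Epochs span
-1..3 s around the locking event, baseline correction subtracts the mean
of -0.3..-0.1 s, and oscillatory power uses a Hanning-taper FFT with an
adaptive five-cycle window per frequency (dt = 5/f) stepped every 20 ms.
Time points whose window does not fit inside the epoch are NaN rather than
zero-padded, so the baseline is never biased by edge effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, firwin

from .io import EventList, Recording

__all__ = [
    "EpochSet",
    "TFR",
    "downsample",
    "epoch",
    "baseline_correct",
    "erp",
    "find_deflection_window",
    "tfr_hanning",
    "tfr_relchange",
]


@dataclass
class EpochSet:
    """Trial-locked slices: (trials, channels, time) in µV."""

    data: np.ndarray
    times: np.ndarray  # s relative to the lock event
    fs: float
    condition: np.ndarray  # per-trial labels
    lock: str = "cue"
    channels: list | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class TFR:
    """(trials, channels, freqs, times) power array."""

    data: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    fs: float
    condition: np.ndarray
    normalization: str = "raw"  # or "relchange"


def downsample(rec: Recording, target_fs: float = 100.0) -> Recording:
    """Anti-aliased decimation to ``target_fs`` (integer ratio required).

    Zero-phase FIR low-pass at 0.8x the target Nyquist, then slicing.
    """
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs {rec.fs} not an integer multiple of {target_fs}")
    ratio = int(round(ratio))
    if ratio == 1:
        return rec
    cutoff = 0.8 * (target_fs / 2)
    ntaps = int(4 * rec.fs / cutoff) | 1
    taps = firwin(ntaps, cutoff, fs=rec.fs)
    filtered = fftconvolve(rec.signal, taps[None, :], mode="same", axes=1)
    return Recording(
        signal=filtered[:, ::ratio],
        fs=target_fs,
        channels=list(rec.channels),
        t0=rec.t0,
    )


def epoch(
    rec: Recording,
    events,
    window: tuple[float, float] = (-1.0, 3.0),
    lock: str = "cue",
    conditions=None,
) -> EpochSet:
    """Slice trials around event onsets at sample resolution.

    ``events`` is an EventList (kept cues only) or an array of lock times
    in seconds with ``conditions`` labels.  Events whose window does not
    fit inside the recording are dropped with a warning.
    """
    if isinstance(events, EventList):
        sel = events.kept
        times_s = events.onset_s[sel]
        conds = events.condition[sel]
    else:
        times_s = np.asarray(events, dtype=float)
        conds = (
            np.asarray(conditions, dtype=object)
            if conditions is not None
            else np.array(["all"] * len(times_s), dtype=object)
        )
    fs = rec.fs
    i_start = np.round((times_s + window[0]) * fs).astype(int)
    n_samp = int(round((window[1] - window[0]) * fs))
    ok = (i_start >= 0) & (i_start + n_samp <= rec.n_samples)
    if not ok.all():
        warnings.warn(
            f"dropped {int((~ok).sum())} events with partial windows", stacklevel=2
        )
    if not ok.any():
        raise ValueError("no events with a full epoch window")
    idx = i_start[ok][:, None] + np.arange(n_samp)[None, :]
    data = rec.signal[:, idx].transpose(1, 0, 2)  # trials x channels x time
    times = window[0] + np.arange(n_samp) / fs
    return EpochSet(
        data=data,
        times=times,
        fs=fs,
        condition=conds[ok],
        lock=lock,
        channels=list(rec.channels),
    )


def baseline_correct(ep: EpochSet, base: tuple[float, float] = (-0.3, -0.1)) -> EpochSet:
    """Subtract the per-trial, per-channel mean of the baseline window."""
    sel = (ep.times >= base[0]) & (ep.times < base[1])
    if not sel.any():
        raise ValueError("baseline window outside the epoch")
    corrected = ep.data - ep.data[:, :, sel].mean(axis=2, keepdims=True)
    return EpochSet(
        data=corrected,
        times=ep.times,
        fs=ep.fs,
        condition=ep.condition,
        lock=ep.lock,
        channels=ep.channels,
    )


def erp(ep: EpochSet, average_channels: bool = True):
    """Per-condition trial-average waveform.

    Returns ``(waves, counts)``; ``waves[cond]`` is (time,) when channels
    are averaged, else (channels, time).
    """
    waves, counts = {}, {}
    for cond in np.unique(ep.condition):
        sel = ep.condition == cond
        w = ep.data[sel].mean(axis=0)
        if average_channels:
            w = w.mean(axis=0)
        waves[str(cond)] = w
        counts[str(cond)] = int(sel.sum())
    return waves, counts


def find_deflection_window(
    subject_erps: np.ndarray,
    times: np.ndarray,
    cfg=None,
):
    """Data-driven windows where the group ERP differs from zero.

    ``subject_erps`` is (subjects, time): per-participant across-condition
    ERPs.  A one-sample cluster permutation test against zero returns the
    significant time clusters; the trough window is the negative-tail
    cluster.  Returns a list of ``(t_start, t_end, sign)`` tuples (empty
    when nothing is significant).
    """
    from .cluster import PermutationConfig, cbp_one_sample

    cfg = cfg or PermutationConfig()
    res = cbp_one_sample(subject_erps, cfg)
    out = []
    for c in res.significant(cfg.alpha):
        t = times[c.indices]
        out.append((float(t.min()), float(t.max()), c.sign))
    return out


def tfr_hanning(
    ep: EpochSet,
    freqs=None,
    cycles: float = 5.0,
    step_s: float = 0.02,
) -> TFR:
    """Hanning-taper FFT power with an adaptive five-cycle window.

    Per frequency f the window length is ``cycles / f`` seconds, centered
    on output points every ``step_s``.  Power is the squared amplitude of
    the taper-weighted Fourier coefficient at f (amplitude-normalized so a
    unit sinusoid at f yields power 1 within taper leakage).  Output
    points whose window spills past the epoch edges are NaN.
    """
    freqs = np.asarray(freqs if freqs is not None else np.arange(5.0, 31.0), float)
    fs = ep.fs
    if ep.times[-1] - ep.times[0] < cycles / freqs.min():
        raise ValueError("epoch shorter than the longest analysis window")
    step = int(round(step_s * fs))
    centers = np.arange(0, len(ep.times), step)
    out_times = ep.times[centers]
    n_tr, n_ch, _ = ep.data.shape
    power = np.full((n_tr, n_ch, len(freqs), len(centers)), np.nan)
    for fi, f in enumerate(freqs):
        nw = int(round(cycles / f * fs))
        taper = np.hanning(nw)
        # complex exponential weights; normalize so |coef| = sinusoid amplitude
        t_win = np.arange(nw) / fs
        weights = taper * np.exp(-2j * np.pi * f * t_win) * (2.0 / taper.sum())
        half = nw // 2
        valid = (centers - half >= 0) & (centers - half + nw <= len(ep.times))
        vc = centers[valid]
        if vc.size == 0:
            continue
        seg_idx = (vc - half)[:, None] + np.arange(nw)[None, :]
        segs = ep.data[:, :, seg_idx]  # trials x ch x centers x nw
        coef = segs @ weights
        power[:, :, fi, valid] = np.abs(coef) ** 2
    return TFR(
        data=power,
        times=out_times,
        freqs=freqs,
        fs=fs,
        condition=ep.condition,
        normalization="raw",
    )


def tfr_relchange(tfr: TFR, base: tuple[float, float] = (-0.3, -0.1)) -> TFR:
    """Baseline relative change of power: (P - P_base) / P_base.

    The baseline mean is taken per trial, channel and frequency over the
    finite samples of the baseline window.
    """
    if tfr.normalization != "raw":
        raise ValueError("expected raw power")
    sel = (tfr.times >= base[0]) & (tfr.times < base[1])
    base_vals = tfr.data[:, :, :, sel]
    if not sel.any() or np.all(np.isnan(base_vals)):
        raise ValueError("no finite baseline samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base_mean = np.nanmean(base_vals, axis=3, keepdims=True)
    if np.any(base_mean == 0):
        raise ValueError("zero baseline power")
    return TFR(
        data=(tfr.data - base_mean) / base_mean,
        times=tfr.times,
        freqs=tfr.freqs,
        fs=tfr.fs,
        condition=tfr.condition,
        normalization="relchange",
    )
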