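"""A7-style spindle detection from three simultaneous decision signals.

Per channel, three time series are computed on the NREM2-3 data and
interpolated to the signal sampling grid:

* ``relpow`` — relative sigma power: 12-16 Hz power over 1-30 Hz power
  from short-time Fourier transforms (2-s Hanning windows, 200 ms step);
* ``mrms``  — moving RMS of the sigma-filtered trace (300 ms window,
  100 ms step);
* ``mcorr`` — moving Pearson correlation between the broadband (1-30 Hz)
  and sigma-filtered traces (300 ms window, 100 ms step).

A spindle candidate is any run where simultaneously relpow > 0.2, mrms
exceeds its own mean + 1.5 SD (over all masked samples of that channel),
and mcorr > 0.65.  Candidates shorter than 0.5 s or longer than 2 s are
discarded.  Events on different channels whose onsets fall within 500 ms
are merged (transitive closure) into a single multichannel spindle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .filters import design_bandpass
from .io import IntervalSet, Recording

__all__ = [
    "SpindleDetectionParams",
    "decision_signals",
    "detect_spindles",
    "merge_across_channels",
    "spindle_features",
]


@dataclass
class SpindleDetectionParams:
    sigma_band_hz: tuple[float, float] = (12.0, 16.0)
    broad_band_hz: tuple[float, float] = (1.0, 30.0)
    stft_window_s: float = 2.0
    stft_step_s: float = 0.2
    relpow_thresh: float = 0.2
    rms_window_s: float = 0.3
    rms_step_s: float = 0.1
    rms_sd_mult: float = 1.5
    corr_window_s: float = 0.3
    corr_step_s: float = 0.1
    corr_thresh: float = 0.65
    duration_s: tuple[float, float] = (0.5, 2.0)
    merge_window_s: float = 0.5

    def __post_init__(self) -> None:
        if self.duration_s[0] > self.duration_s[1]:
            raise ValueError("duration bounds not ordered")
        for v in (self.relpow_thresh, self.corr_thresh, self.rms_sd_mult):
            if v <= 0:
                raise ValueError("thresholds must be positive")


def _moving_windows(n: int, win: int, step: int):
    starts = np.arange(0, n - win + 1, step)
    return starts, starts + win // 2  # window starts and center samples


def _interp_to_samples(centers: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    if len(centers) == 0:
        return np.full(n, np.nan)
    return np.interp(np.arange(n), centers, values, left=values[0], right=values[-1])


def _band_filters(fs: float, params: SpindleDetectionParams):
    sigma = design_bandpass(fs, *params.sigma_band_hz)
    broad = design_bandpass(fs, *params.broad_band_hz)
    return sigma, broad


def decision_signals(
    rec: Recording, params: SpindleDetectionParams | None = None
) -> dict[str, np.ndarray]:
    """The three decision signals per channel, on the sample grid.

    Returns ``{"relpow": (ch, n), "mrms": (ch, n), "mcorr": (ch, n)}``.
    """
    params = params or SpindleDetectionParams()
    fs = rec.fs
    n = rec.n_samples
    win_stft = int(round(params.stft_window_s * fs))
    if n < win_stft:
        raise ValueError("segment shorter than the STFT window")
    sigma_f, broad_f = _band_filters(fs, params)
    out = {k: np.empty((len(rec.channels), n)) for k in ("relpow", "mrms", "mcorr")}
    step_stft = int(round(params.stft_step_s * fs))
    for ci in range(len(rec.channels)):
        x = rec.signal[ci]
        xs = sigma_f.apply(x)
        xb = broad_f.apply(x)

        # relative sigma power from STFT
        starts, centers = _moving_windows(n, win_stft, step_stft)
        taper = np.hanning(win_stft)
        freqs = np.fft.rfftfreq(win_stft, 1 / fs)
        in_sigma = (freqs >= params.sigma_band_hz[0]) & (freqs <= params.sigma_band_hz[1])
        in_broad = (freqs >= params.broad_band_hz[0]) & (freqs <= params.broad_band_hz[1])
        segs = x[starts[:, None] + np.arange(win_stft)[None, :]] * taper
        psd = np.abs(np.fft.rfft(segs, axis=1)) ** 2
        denom = psd[:, in_broad].sum(axis=1)
        denom[denom == 0] = np.inf
        relpow = psd[:, in_sigma].sum(axis=1) / denom
        out["relpow"][ci] = _interp_to_samples(centers, relpow, n)

        # moving RMS of the sigma-filtered trace
        win = int(round(params.rms_window_s * fs))
        step = int(round(params.rms_step_s * fs))
        starts, centers = _moving_windows(n, win, step)
        segs = xs[starts[:, None] + np.arange(win)[None, :]]
        mrms = np.sqrt(np.mean(segs**2, axis=1))
        out["mrms"][ci] = _interp_to_samples(centers, mrms, n)

        # moving broadband-sigma correlation
        win = int(round(params.corr_window_s * fs))
        step = int(round(params.corr_step_s * fs))
        starts, centers = _moving_windows(n, win, step)
        a = xb[starts[:, None] + np.arange(win)[None, :]]
        b = xs[starts[:, None] + np.arange(win)[None, :]]
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
        denom[denom == 0] = np.inf
        mcorr = (a * b).sum(axis=1) / denom
        out["mcorr"][ci] = _interp_to_samples(centers, mcorr, n)
    return out


_COLUMNS = [
    "channel",
    "start_s",
    "end_s",
    "duration_s",
    "amplitude_uv",
    "frequency_hz",
]


def detect_spindles(
    rec: Recording,
    mask: np.ndarray | None = None,
    params: SpindleDetectionParams | None = None,
    signals: dict | None = None,
) -> pd.DataFrame:
    """Per-channel spindle events from the three decision signals.

    The RMS threshold (mean + 1.5 SD) is estimated per channel over all
    masked samples, so stimulation and rest intervals share one reference.
    Amplitude is the peak-to-peak of the sigma-filtered trace over the
    event; frequency the mean instantaneous frequency of its analytic
    signal.
    """
    params = params or SpindleDetectionParams()
    if mask is None:
        mask = np.ones(rec.n_samples, dtype=bool)
    signals = signals if signals is not None else decision_signals(rec, params)
    fs = rec.fs
    sigma_f, _ = _band_filters(fs, params)
    rows = []
    for ci, ch in enumerate(rec.channels):
        mrms = signals["mrms"][ci]
        ref = mrms[mask]
        rms_thresh = ref.mean() + params.rms_sd_mult * ref.std()
        hit = (
            (signals["relpow"][ci] > params.relpow_thresh)
            & (mrms > rms_thresh)
            & (signals["mcorr"][ci] > params.corr_thresh)
            & mask
        )
        if not hit.any():
            continue
        # run-length extraction
        d = np.diff(np.r_[0, hit.astype(int), 0])
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)  # exclusive
        xs = sigma_f.apply(rec.signal[ci])
        analytic = hilbert(xs)
        inst_freq = np.gradient(np.unwrap(np.angle(analytic))) * fs / (2 * np.pi)
        for s, e in zip(run_starts, run_ends):
            dur = (e - s) / fs
            if not (params.duration_s[0] <= dur <= params.duration_s[1]):
                continue
            seg = xs[s:e]
            rows.append(
                (
                    ch,
                    s / fs,
                    e / fs,
                    dur,
                    float(seg.max() - seg.min()),
                    float(inst_freq[s:e].mean()),
                )
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def merge_across_channels(
    events: pd.DataFrame, merge_window_s: float = 0.5
) -> pd.DataFrame:
    """Union events whose onsets lie within the merge window (transitive).

    The merged event spans min start to max end, lists the contributing
    channels, and carries the amplitude of the largest member and the
    member-mean frequency.  Idempotent and order-independent.
    """
    if events.empty:
        return events.assign(channels=pd.Series(dtype=object))
    ev = events.sort_values("start_s").reset_index(drop=True)
    if "channels" not in ev:
        ev = ev.assign(channels=[[c] for c in ev["channel"].astype(str)])
    onsets = ev["start_s"].to_numpy()
    group = np.zeros(len(ev), dtype=int)
    g = 0
    for i in range(1, len(ev)):
        if onsets[i] - onsets[i - 1] <= merge_window_s:
            group[i] = g
        else:
            g += 1
            group[i] = g
    rows = []
    for _, grp in ev.groupby(group):
        chans = sorted({c for lst in grp["channels"] for c in lst})
        rows.append(
            {
                "channel": "+".join(chans),
                "channels": chans,
                "start_s": float(grp["start_s"].min()),
                "end_s": float(grp["end_s"].max()),
                "duration_s": float(grp["end_s"].max() - grp["start_s"].min()),
                "amplitude_uv": float(grp["amplitude_uv"].max()),
                "frequency_hz": float(grp["frequency_hz"].mean()),
            }
        )
    return pd.DataFrame(rows)


def spindle_features(events: pd.DataFrame, intervals: IntervalSet) -> pd.DataFrame:
    """Per-kind density (/min), mean amplitude (µV) and frequency (Hz).

    Events are assigned by onset time; zero-denominator kinds are flagged.
    """
    totals = intervals.totals_min()
    assigned = np.asarray(
        [intervals.kind_at(t) for t in events["start_s"]] if len(events) else [],
        dtype=object,
    )
    rows = []
    for kind in sorted(totals):
        sel = assigned == kind if assigned.size else np.zeros(0, bool)
        n = int(sel.sum())
        minutes = totals[kind]
        sub = events[sel] if n else events.iloc[:0]
        rows.append(
            {
                "kind": kind,
                "count": n,
                "minutes": minutes,
                "density_per_min": n / minutes if minutes > 0 else np.nan,
                "mean_amplitude_uv": float(sub["amplitude_uv"].mean()) if n else np.nan,
                "mean_frequency_hz": float(sub["frequency_hz"].mean()) if n else np.nan,
                "undefined_denominator": minutes <= 0,
            }
        )
    return pd.DataFrame(rows).set_index("kind")
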