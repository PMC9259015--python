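"""Slow-wave detection by filtering, candidate peaks and logical thresholds.

The trace is band-passed 0.3-2 Hz with a 0.2 Hz transition (half-amplitude
points at 0.2 and 2.1 Hz) and, per channel, candidate negative peaks
(-40..-200 µV) are paired with the next candidate positive peak
(10..150 µV).  Five logical thresholds then validate each pair:

1. negative half-wave duration 0.3-1.5 s (between the zero-crossings
   flanking the negative peak);
2. positive half-wave duration 0.1-1 s;
3. negative amplitude 40-300 µV;
4. positive amplitude 10-200 µV;
5. peak-to-peak (PTP) amplitude 75-500 µV.

The candidate peak-picking ranges and the logical amplitude bounds differ
on purpose: candidates are picked with the narrow ranges, validation then
applies the wider logical bounds, in that order.  Both are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .filters import FIRFilter, design_bandpass
from .io import IntervalSet, Recording

__all__ = [
    "SWDetectionParams",
    "design_sw_filter",
    "detect_slow_waves",
    "sw_features",
    "check_sw_thresholds",
]


@dataclass
class SWDetectionParams:
    band_hz: tuple[float, float] = (0.3, 2.0)
    transition_hz: float = 0.2
    cand_neg_uv: tuple[float, float] = (40.0, 200.0)  # |negative peak| pick range
    cand_pos_uv: tuple[float, float] = (10.0, 150.0)
    neg_dur_s: tuple[float, float] = (0.3, 1.5)
    pos_dur_s: tuple[float, float] = (0.1, 1.0)
    neg_amp_uv: tuple[float, float] = (40.0, 300.0)
    pos_amp_uv: tuple[float, float] = (10.0, 200.0)
    ptp_uv: tuple[float, float] = (75.0, 500.0)

    def __post_init__(self) -> None:
        for name in (
            "cand_neg_uv",
            "cand_pos_uv",
            "neg_dur_s",
            "pos_dur_s",
            "neg_amp_uv",
            "pos_amp_uv",
            "ptp_uv",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range not ordered")
        if self.ptp_uv[0] < 0:
            raise ValueError("PTP lower bound must be >= 0")


def design_sw_filter(fs: float, params: SWDetectionParams | None = None) -> FIRFilter:
    """The detection band-pass; see the module docstring for its spec."""
    params = params or SWDetectionParams()
    return design_bandpass(fs, *params.band_hz, trans=params.transition_hz)


_COLUMNS = [
    "channel",
    "start_s",
    "neg_peak_s",
    "zero_cross_s",
    "pos_peak_s",
    "end_s",
    "neg_amp_uv",
    "pos_amp_uv",
    "ptp_uv",
]


def detect_slow_waves(
    rec: Recording,
    mask: np.ndarray | None = None,
    params: SWDetectionParams | None = None,
    sw_filter: FIRFilter | None = None,
) -> pd.DataFrame:
    """Detect slow waves per channel inside the NREM2-3 mask.

    Returns a DataFrame with one row per event: channel, the five landmark
    times (negative-wave start, negative peak, zero-crossing, positive
    peak, positive-wave end; seconds) and the amplitude features.  Events
    whose span touches a mask boundary are discarded (no partial waves).
    """
    params = params or SWDetectionParams()
    filt = sw_filter or design_sw_filter(rec.fs, params)
    if mask is None:
        mask = np.ones(rec.n_samples, dtype=bool)
    fs = rec.fs
    rows = []
    for ci, ch in enumerate(rec.channels):
        xf = filt.apply(rec.signal[ci])
        neg_idx, _ = find_peaks(-xf, height=params.cand_neg_uv)
        pos_idx, _ = find_peaks(xf, height=params.cand_pos_uv)
        if neg_idx.size == 0 or pos_idx.size == 0:
            continue
        # zero-crossing sample indices (last sample before the sign change)
        sign = np.signbit(xf)
        zc = np.flatnonzero(sign[1:] != sign[:-1])
        for ni in neg_idx:
            # pair with the next candidate positive peak
            pj = pos_idx[np.searchsorted(pos_idx, ni)] if np.searchsorted(
                pos_idx, ni
            ) < len(pos_idx) else None
            if pj is None:
                continue
            before = zc[zc < ni]
            between = zc[(zc >= ni) & (zc < pj)]
            after = zc[zc >= pj]
            if before.size == 0 or between.size == 0 or after.size == 0:
                continue
            start, mid, end = before[-1], between[0], after[0]
            neg_dur = (mid - start) / fs
            pos_dur = (end - mid) / fs
            neg_amp = -xf[ni]
            pos_amp = xf[pj]
            ptp = neg_amp + pos_amp
            if not (params.neg_dur_s[0] <= neg_dur <= params.neg_dur_s[1]):
                continue
            if not (params.pos_dur_s[0] <= pos_dur <= params.pos_dur_s[1]):
                continue
            if not (params.neg_amp_uv[0] <= neg_amp <= params.neg_amp_uv[1]):
                continue
            if not (params.pos_amp_uv[0] <= pos_amp <= params.pos_amp_uv[1]):
                continue
            if not (params.ptp_uv[0] <= ptp <= params.ptp_uv[1]):
                continue
            if not mask[start : end + 1].all():
                continue  # partial wave at a mask boundary
            rows.append(
                (
                    ch,
                    start / fs,
                    ni / fs,
                    mid / fs,
                    pj / fs,
                    end / fs,
                    float(neg_amp),
                    float(pos_amp),
                    float(ptp),
                )
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def check_sw_thresholds(
    events: pd.DataFrame, rec: Recording, params: SWDetectionParams | None = None
) -> pd.DataFrame:
    """Independent re-check of the five logical thresholds per event.

    Re-filters the signal and verifies durations, amplitudes and PTP from
    the stored landmark times; used as a brute-force audit of the
    detector.  Returns a boolean frame, one column per threshold.
    """
    params = params or SWDetectionParams()
    filt = design_sw_filter(rec.fs, params)
    traces = {ch: filt.apply(rec.signal[i]) for i, ch in enumerate(rec.channels)}
    fs = rec.fs
    out = []
    for _, ev in events.iterrows():
        xf = traces[ev["channel"]]
        neg_amp = -xf[int(round(ev["neg_peak_s"] * fs))]
        pos_amp = xf[int(round(ev["pos_peak_s"] * fs))]
        out.append(
            {
                "neg_dur_ok": params.neg_dur_s[0]
                <= ev["zero_cross_s"] - ev["start_s"]
                <= params.neg_dur_s[1],
                "pos_dur_ok": params.pos_dur_s[0]
                <= ev["end_s"] - ev["zero_cross_s"]
                <= params.pos_dur_s[1],
                "neg_amp_ok": params.neg_amp_uv[0] <= neg_amp <= params.neg_amp_uv[1],
                "pos_amp_ok": params.pos_amp_uv[0] <= pos_amp <= params.pos_amp_uv[1],
                "ptp_ok": params.ptp_uv[0] <= neg_amp + pos_amp <= params.ptp_uv[1],
            }
        )
    return pd.DataFrame(out, dtype=bool)


def sw_features(events: pd.DataFrame, intervals: IntervalSet) -> pd.DataFrame:
    """Per interval-kind SW density (events/min) and mean PTP amplitude.

    Events are assigned to the interval containing their negative peak;
    kinds with zero total minutes get NaN density and a flag.
    """
    totals = intervals.totals_min()
    kinds = sorted(totals)
    assigned = (
        [intervals.kind_at(t) for t in events["neg_peak_s"]]
        if len(events)
        else []
    )
    assigned = np.asarray(assigned, dtype=object)
    ptp = events["ptp_uv"].to_numpy(float) if len(events) else np.empty(0)
    rows = []
    for kind in kinds:
        sel = assigned == kind if assigned.size else np.zeros(0, bool)
        n = int(sel.sum())
        minutes = totals[kind]
        rows.append(
            {
                "kind": kind,
                "count": n,
                "minutes": minutes,
                "density_per_min": n / minutes if minutes > 0 else np.nan,
                "mean_ptp_uv": float(ptp[sel].mean()) if n else np.nan,
                "undefined_denominator": minutes <= 0,
            }
        )
    return pd.DataFrame(rows).set_index("kind")
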