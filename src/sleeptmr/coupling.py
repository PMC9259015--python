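"""Event-related phase-amplitude coupling (ERPAC) and circular inference.

The instantaneous phase of the slow oscillation (0.5-2 Hz) and the
amplitude envelopes of the signal in 1-Hz-spaced bands between 7 and 30 Hz
are extracted by Hilbert transform from the *continuous* channel-averaged
trace (filtering before epoching avoids edge artifacts), then cut into
trials around the events of interest.  At every (frequency, time) point
the coupling strength across trials is the circular-linear correlation

    rho = sqrt((r_ac^2 + r_as^2 - 2 r_ac r_as r_cs) / (1 - r_cs^2))

with r_ac = corr(amp, cos phi), r_as = corr(amp, sin phi) and
r_cs = corr(cos phi, sin phi).  The preferred phase (PP) is the centre of
the phase bin with maximal mean amplitude, and circular inference uses the
Rayleigh test for non-uniformity and the Watson-Williams test for equal
circular means.

Phase convention: analytic-signal phase of the band-passed trace, 0 at
the positive peak and ±pi at the trough.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import hilbert

from .filters import design_bandpass
from .io import Recording

__all__ = [
    "PhaseAmplitudeEpochs",
    "ERPACMap",
    "PreferredPhase",
    "extract_phase_amplitude",
    "phase_amplitude_from_trials",
    "erpac",
    "erpac_from_arrays",
    "preferred_phase",
    "rayleigh_test",
    "watson_williams",
]


@dataclass
class PhaseAmplitudeEpochs:
    phase: np.ndarray  # (trials, time), rad in (-pi, pi]
    amplitude: np.ndarray  # (trials, freqs, time), >= 0
    times: np.ndarray
    freqs: np.ndarray
    condition: np.ndarray
    lock: str = "cue"


@dataclass
class ERPACMap:
    rho: np.ndarray  # (freqs, time) in [0, 1]
    times: np.ndarray
    freqs: np.ndarray
    n_trials: int
    lock: str = "cue"


@dataclass
class PreferredPhase:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    mean_amplitude: np.ndarray
    pp_rad: float
    resultant_length: float


def extract_phase_amplitude(
    rec: Recording,
    event_times_s: np.ndarray,
    window: tuple[float, float] = (-0.5, 2.5),
    phase_band_hz: tuple[float, float] = (0.5, 2.0),
    amp_centers_hz=None,
    amp_halfwidth_hz: float = 2.0,
    conditions=None,
    lock: str = "cue",
    min_trials: int = 30,
) -> PhaseAmplitudeEpochs:
    """Hilbert phase/amplitude around events, from channel-averaged data.

    Events closer than 2 s to either recording edge (plus the window
    margin) are rejected to keep the transform clean.
    """
    amp_centers = np.asarray(
        amp_centers_hz if amp_centers_hz is not None else np.arange(7.0, 31.0), float
    )
    fs = rec.fs
    x = rec.signal.mean(axis=0)
    n = len(x)

    phase_f = design_bandpass(fs, *phase_band_hz)
    phase_cont = np.angle(hilbert(phase_f.apply(x)))
    amp_cont = np.empty((len(amp_centers), n))
    for fi, f in enumerate(amp_centers):
        bf = design_bandpass(fs, f - amp_halfwidth_hz, f + amp_halfwidth_hz)
        amp_cont[fi] = np.abs(hilbert(bf.apply(x)))

    event_times_s = np.asarray(event_times_s, float)
    margin = 2.0
    ok = (event_times_s + window[0] - margin >= 0) & (
        event_times_s + window[1] + margin <= n / fs
    )
    if not ok.any():
        raise ValueError("no events far enough from the recording edges")
    times = np.arange(round(window[0] * fs), round(window[1] * fs)) / fs
    i0 = np.round(event_times_s[ok] * fs).astype(int) + int(round(window[0] * fs))
    idx = i0[:, None] + np.arange(len(times))[None, :]
    conds = (
        np.asarray(conditions, dtype=object)[ok]
        if conditions is not None
        else np.array(["all"] * int(ok.sum()), dtype=object)
    )
    if len(i0) < min_trials:
        raise ValueError(f"only {len(i0)} trials; need >= {min_trials}")
    return PhaseAmplitudeEpochs(
        phase=phase_cont[idx],
        amplitude=amp_cont[:, idx].transpose(1, 0, 2),
        times=times,
        freqs=amp_centers,
        condition=conds,
        lock=lock,
    )


def phase_amplitude_from_trials(
    epochs: np.ndarray,
    times: np.ndarray,
    fs: float,
    crop: tuple[float, float],
    phase_band_hz: tuple[float, float] = (0.5, 2.0),
    amp_centers_hz=None,
    amp_halfwidth_hz: float = 2.0,
    conditions=None,
    lock: str = "cue",
) -> PhaseAmplitudeEpochs:
    """Phase/amplitude extraction from already-cut trials.

    Each (trials, time) epoch is filtered and Hilbert-transformed along
    time, then cropped to ``crop``; the epochs must extend at least half
    the filter length beyond the crop on both sides so the analysis
    window is free of edge artifacts.
    """
    from .filters import apply_zero_phase

    amp_centers = np.asarray(
        amp_centers_hz if amp_centers_hz is not None else np.arange(7.0, 31.0), float
    )
    epochs = np.atleast_2d(np.asarray(epochs, float))
    phase_f = design_bandpass(fs, *phase_band_hz)
    margin_s = (len(phase_f.taps) // 2) / fs
    if times[0] > crop[0] - margin_s or times[-1] < crop[1] + margin_s:
        raise ValueError(
            f"epochs must extend {margin_s:.1f} s beyond the crop window"
        )
    sel = (times >= crop[0]) & (times < crop[1])
    phase = np.angle(hilbert(phase_f.apply(epochs), axis=-1))[:, sel]
    amp = np.empty((epochs.shape[0], len(amp_centers), int(sel.sum())))
    for fi, f in enumerate(amp_centers):
        bf = design_bandpass(fs, f - amp_halfwidth_hz, f + amp_halfwidth_hz)
        amp[:, fi] = np.abs(hilbert(bf.apply(epochs), axis=-1))[:, sel]
    conds = (
        np.asarray(conditions, dtype=object)
        if conditions is not None
        else np.array(["all"] * epochs.shape[0], dtype=object)
    )
    return PhaseAmplitudeEpochs(
        phase=phase,
        amplitude=amp,
        times=times[sel],
        freqs=amp_centers,
        condition=conds,
        lock=lock,
    )


def _corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation along axis 0 with broadcasting, 0 when degenerate."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = (a * b).sum(axis=0)
    den = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def erpac_from_arrays(phase: np.ndarray, amplitude: np.ndarray) -> np.ndarray:
    """Circular-linear correlation across trials (axis 0).

    ``phase``: (trials, ...) broadcastable against ``amplitude``
    (trials, ...).  Returns rho with the trial axis reduced, clipped to
    [0, 1]; points with zero amplitude variance give rho = 0.
    """
    c, s = np.cos(phase), np.sin(phase)
    r_ac = _corr(amplitude, np.broadcast_to(c, amplitude.shape).copy())
    r_as = _corr(amplitude, np.broadcast_to(s, amplitude.shape).copy())
    r_cs = _corr(c, s)
    denom = 1.0 - r_cs**2
    denom = np.where(denom <= 0, np.inf, denom)
    rho2 = (r_ac**2 + r_as**2 - 2 * r_ac * r_as * r_cs) / denom
    return np.sqrt(np.clip(rho2, 0.0, 1.0))


def erpac(pae: PhaseAmplitudeEpochs, min_trials: int = 30) -> ERPACMap:
    """ERPAC map: rho per (frequency, time), computed across trials."""
    n = pae.phase.shape[0]
    if n < min_trials:
        raise ValueError(f"{n} trials < minimum {min_trials}")
    rho = erpac_from_arrays(pae.phase[:, None, :], pae.amplitude)
    return ERPACMap(
        rho=rho, times=pae.times, freqs=pae.freqs, n_trials=n, lock=pae.lock
    )


def preferred_phase(
    pae: PhaseAmplitudeEpochs,
    band_hz: tuple[float, float] = (12.0, 16.0),
    n_bins: int = 18,
    time_window=None,
) -> PreferredPhase:
    """Phase bin of maximal band amplitude over pooled (trial, time) samples.

    Ties are broken by the circular mean of the tied bin centres.  The
    resultant length is the amplitude-weighted mean resultant of the
    pooled phases (1 = amplitude fully concentrated at one phase).
    """
    fsel = (pae.freqs >= band_hz[0]) & (pae.freqs <= band_hz[1])
    if not fsel.any():
        raise ValueError("no amplitude bands inside the requested range")
    tsel = (
        (pae.times >= time_window[0]) & (pae.times < time_window[1])
        if time_window is not None
        else np.ones(len(pae.times), bool)
    )
    amp = pae.amplitude[:, fsel][:, :, tsel].mean(axis=1).ravel()
    phi = pae.phase[:, tsel].ravel()

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(phi, edges) - 1, 0, n_bins - 1)
    mean_amp = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            mean_amp[b] = amp[sel].mean()
    if np.all(np.isnan(mean_amp)):
        raise ValueError("all phase bins empty")
    best = np.nanmax(mean_amp)
    tied = np.flatnonzero(np.isclose(mean_amp, best))
    if len(tied) == 1:
        pp = float(centers[tied[0]])
    else:
        pp = float(np.angle(np.exp(1j * centers[tied]).mean()))
    w = amp.sum()
    resultant = float(np.abs((amp * np.exp(1j * phi)).sum()) / w) if w > 0 else 0.0
    return PreferredPhase(
        bin_edges=edges,
        bin_centers=centers,
        mean_amplitude=mean_amp,
        pp_rad=pp,
        resultant_length=resultant,
    )


def rayleigh_test(phases: np.ndarray, weights: np.ndarray | None = None):
    """Rayleigh test of circular non-uniformity.

    Returns ``(R, z, p)`` with R the (optionally weighted) mean resultant
    length, z = n R^2 and the standard finite-n p approximation
    ``p = exp(-z) * (1 + (2z - z^2)/(4n))`` (clipped to [0, 1]).
    """
    phases = np.asarray(phases, float)
    n = len(phases)
    if n < 10:
        raise ValueError("Rayleigh test needs n >= 10")
    if weights is None:
        r = np.abs(np.exp(1j * phases).mean())
    else:
        w = np.asarray(weights, float)
        r = float(np.abs((w * np.exp(1j * phases)).sum()) / w.sum())
    z = n * r**2
    p = np.exp(-z) * (1 + (2 * z - z**2) / (4 * n))
    return float(r), float(z), float(min(max(p, 0.0), 1.0))


def _circ_mean_R(phases: np.ndarray):
    z = np.exp(1j * np.asarray(phases, float)).mean()
    return np.angle(z), np.abs(z)


def _kappa_from_R(R: float) -> float:
    # standard maximum-likelihood approximation for the von Mises kappa
    if R < 0.53:
        return 2 * R + R**3 + 5 * R**5 / 6
    if R < 0.85:
        return -0.4 + 1.39 * R + 0.43 / (1 - R)
    return 1 / (R**3 - 4 * R**2 + 3 * R)


def watson_williams(*groups, warn_concentration: bool = True):
    """Watson-Williams test for equality of circular means across groups.

    Circular one-way ANOVA with the standard kappa-based correction
    factor; assumes comparable concentrations and mean resultant length
    R >= 0.45 (a UserWarning is raised below that).  Returns ``(F, p)``.
    """
    import warnings

    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([len(g) for g in groups])
    if np.any(ns < 5):
        raise ValueError("each group needs n >= 5")
    N = ns.sum()
    k = len(groups)
    Rs = np.array([len(g) * _circ_mean_R(g)[1] for g in groups])  # n_i * R_i
    all_phases = np.concatenate(groups)
    _, R_bar_all = _circ_mean_R(all_phases)
    R_all = N * R_bar_all
    rw = Rs.sum() / N  # weighted mean resultant length
    if warn_concentration and rw < 0.45:
        warnings.warn(
            f"mean resultant length {rw:.2f} < 0.45; Watson-Williams "
            "assumptions are doubtful",
            stacklevel=2,
        )
    kappa = _kappa_from_R(rw)
    correction = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    num = (Rs.sum() - R_all) / (k - 1)
    den = (N - Rs.sum()) / (N - k)
    if den <= 0:
        return np.inf, 0.0
    F = correction * num / den
    p = float(stats.f.sf(F, k - 1, N - k))
    return float(F), p
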