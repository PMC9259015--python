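"""Zero-phase FIR filtering shared by the detection and coupling stages.

Filters are windowed-sinc (firwin) designs whose half-amplitude (-6 dB)
points sit half a transition band outside each passband edge.  Taps are
symmetric and odd-length, so a single 'same'-mode convolution applies
them with zero phase delay and event landmark times are not lag-shifted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, freqz

__all__ = ["FIRFilter", "design_bandpass", "apply_zero_phase"]


@dataclass
class FIRFilter:
    taps: np.ndarray
    fs: float
    band: tuple[float, float]

    def response(self, freqs) -> np.ndarray:
        """Magnitude response |H(f)| at the requested frequencies (Hz)."""
        _, h = freqz(self.taps, worN=np.asarray(freqs, float), fs=self.fs)
        return np.abs(h)

    def half_amplitude_points(self, n_grid: int = 2**17) -> tuple[float, float]:
        """Frequencies where |H| crosses 0.5, from a fine response grid."""
        w, h = freqz(self.taps, worN=n_grid, fs=self.fs)
        mag = np.abs(h)
        crossings = np.flatnonzero(np.diff(np.sign(mag - 0.5)))
        if len(crossings) < 2:
            raise RuntimeError("response does not bracket half amplitude twice")

        def interp(i):
            f0, f1 = w[i], w[i + 1]
            m0, m1 = mag[i], mag[i + 1]
            return f0 + (0.5 - m0) * (f1 - f0) / (m1 - m0)

        return float(interp(crossings[0])), float(interp(crossings[-1]))

    def apply(self, x: np.ndarray) -> np.ndarray:
        return apply_zero_phase(x, self.taps)


def design_bandpass(
    fs: float,
    low: float,
    high: float,
    trans: float = None,
) -> FIRFilter:
    """Linear-phase FIR band-pass with -6 dB at ``low - trans/2`` and
    ``high + trans/2``.

    ``trans`` defaults to MNE's adaptive choice; the slow-wave detection
    stage passes 0.2 Hz explicitly to pin the -6 dB points at 0.2 and
    2.1 Hz for the 0.3-2 Hz band.
    """
    if fs <= 2 * high:
        raise ValueError("sampling rate must exceed twice the upper edge")
    if trans is not None and trans >= 2 * low:
        raise ValueError("transition band wider than twice the lower edge")
    import mne

    kwargs = {}
    if trans is not None:
        kwargs = {"l_trans_bandwidth": trans, "h_trans_bandwidth": trans}
    taps = mne.filter.create_filter(
        None,
        fs,
        l_freq=low,
        h_freq=high,
        fir_design="firwin",
        verbose="error",
        **kwargs,
    )
    return FIRFilter(taps=np.asarray(taps), fs=fs, band=(low, high))


def apply_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply symmetric odd-length FIR taps with zero delay ('same' conv)."""
    if len(taps) % 2 != 1:
        raise ValueError("taps must be odd-length for zero-phase application")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return fftconvolve(x, taps, mode="same")
    return fftconvolve(x, taps[None, :], mode="same", axes=-1)
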