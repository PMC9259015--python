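"""Event-related phase-amplitude coupling on trials with known coupling.

Generates 300 trials in which sigma (14 Hz) amplitude is modulated by the
slow-oscillation phase (depth 0.8, preferred phase -pi/2 = the falling
zero-crossing after the SO peak), then recovers the coupling strength map
(circular-linear correlation rho across trials), the preferred phase, and
its Rayleigh significance.
"""

import numpy as np

from sleeptmr.coupling import (
    erpac,
    phase_amplitude_from_trials,
    preferred_phase,
    rayleigh_test,
)
from sleeptmr.simulate import simulate_coupled_trials

epochs, times, _ = simulate_coupled_trials(
    n_trials=300, depth=0.8, preferred_phase_rad=-np.pi / 2, carrier_hz=14.0,
    window=(-6, 7), seed=4,
)
pae = phase_amplitude_from_trials(epochs, times, fs=100.0, crop=(-1, 2))
m = erpac(pae)

band = (pae.freqs >= 12) & (pae.freqs <= 16)
print(f"mean rho in 12-16 Hz: {m.rho[band].mean():.3f}")
print(f"mean rho outside (7-9, 20-30 Hz): "
      f"{m.rho[(pae.freqs < 10) | (pae.freqs > 19)].mean():.3f}")

pp = preferred_phase(pae, band_hz=(12, 16), n_bins=18)
R, z, p = rayleigh_test(pae.phase[:, np.argmin(np.abs(pae.times))], None)
print(f"preferred phase: {pp.pp_rad:+.2f} rad (injected -1.57)")
print(f"amplitude-weighted resultant length: {pp.resultant_length:.2f}")
print(
    "\nrho near 1 inside the injected band and near the chance level "
    "(~1.25/sqrt(n)) elsewhere indicates the coupling estimator isolates "
    "the programmed SO-phase/sigma-amplitude relationship."
)
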