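import numpy as np
import pytest

from sleeptmr.io import restrict_to_stages
from sleeptmr.simulate import SimulationConfig, StimSpec, simulate_recording


@pytest.fixture(scope="session")
def highsnr_recording():
    """10 min of N2-3 with embedded events at high SNR, no cue-evoked
    responses: the controlled detector-recovery scenario."""
    cfg = SimulationConfig(
        stage_script=(("N2", 6.0), ("N3", 4.0)),
        background_rms_uv=6.0,
        stim=StimSpec(evoked_uv={"associated": 0.0, "unassociated": 0.0}),
        seed=11,
    )
    rec, hyp, events, truth = simulate_recording(cfg)
    mask = restrict_to_stages(rec, hyp, {"N2", "N3"})
    return cfg, rec, hyp, events, truth, mask


@pytest.fixture(scope="session")
def study_recording():
    """Study-like 12-min nap with wake lead-in, cues and evoked responses."""
    cfg = SimulationConfig(stage_script=(("W", 1.0), ("N2", 7.0), ("N3", 4.0)), seed=7)
    rec, hyp, events, truth = simulate_recording(cfg)
    mask = restrict_to_stages(rec, hyp, {"N2", "N3"})
    return cfg, rec, hyp, events, truth, mask


def match_events(detected_s, true_s, tol_s):
    """(recall, precision) by nearest-time matching within a tolerance."""
    detected_s = np.asarray(detected_s)
    true_s = np.asarray(true_s)
    if len(true_s) == 0 or len(detected_s) == 0:
        return 0.0, 0.0
    tp = sum(np.any(np.abs(detected_s - t) <= tol_s) for t in true_s)
    fp = sum(not np.any(np.abs(true_s - d) <= tol_s) for d in detected_s)
    return tp / len(true_s), 1 - fp / len(detected_s)
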