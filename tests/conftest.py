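import numpy as np
import pytest

from ectopulse import simulate as sim
from ectopulse.io import resample_to_1khz


@pytest.fixture(scope="session")
def sim_patient():
    """One simulated responder: (config, 125 Hz record, ground truth, SV series)."""
    cfg = sim.PatientSimConfig(patient_id="fix1", duration_s=120.0, p_ectopic=0.04)
    rec, hemo, sv = sim.simulate_patient_waveforms(cfg, seed=1234)
    return cfg, rec, hemo, sv


@pytest.fixture(scope="session")
def sim_patient_1k(sim_patient):
    _, rec, hemo, sv = sim_patient
    return resample_to_1khz(rec), hemo, sv


@pytest.fixture(scope="session")
def clean_patient():
    """Noise-free simulated patient (exact label recovery is expected)."""
    cfg = sim.PatientSimConfig(
        patient_id="clean", duration_s=120.0, p_ectopic=0.04,
        ecg_noise=0.0, abp_noise_mmHg=0.0, pep_noise_ms=0.0,
    )
    rec, hemo, sv = sim.simulate_patient_waveforms(cfg, seed=77)
    return cfg, rec, hemo, sv


def brute_force_auc(scores, labels):
    """Pairwise-counting AUC oracle (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
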