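import numpy as np
import pytest

from seeqrs import DetectorConfig, SynthConfig, generate_record


def write_wfdb_pair(directory, record_id, fs, samples_mv, lead_names, gain=2000.0, baseline=0):
    """Write a minimal WFDB header + format-16 signal pair for testing."""
    samples_mv = np.atleast_2d(np.asarray(samples_mv, dtype=float))
    n_sig, n_samp = samples_mv.shape
    hea = directory / f"{record_id}.hea"
    dat = directory / f"{record_id}.dat"
    lines = [f"{record_id} {n_sig} {fs:g} {n_samp}"]
    for name in lead_names:
        lines.append(
            f"{record_id}.dat 16 {gain:g}({baseline})/mV 16 {baseline} 0 0 0 {name}"
        )
    hea.write_text("\n".join(lines) + "\n")
    adc = np.clip(np.round(samples_mv * gain + baseline), -32768, 32767).astype("<i2")
    adc.T.tofile(dat)  # frames interleaved across signals
    return hea


@pytest.fixture(scope="session")
def default_config():
    return DetectorConfig()


@pytest.fixture(scope="session")
def clean_record():
    """30 s clean synthetic lead at 60 bpm with zero RR jitter."""
    return generate_record(
        SynthConfig(duration_s=30.0, rr_jitter_frac=0.0, seed=11)
    )
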