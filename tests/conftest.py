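import numpy as np
import pytest

from rdeco.synthetic import SyntheticSpec, generate_ecg

#: the canonical clean study signal: 5 min, 70 bpm, fs 360 Hz, 30 dB SNR
CLEAN_SPEC = SyntheticSpec(
    duration_s=300.0, fs=360.0, mean_hr_bpm=70.0, hr_sd_bpm=3.0,
    noise_snr_db=30.0, seed=1,
)

#: regular 60 bpm rhythm with premature beats at a 250 ms coupling interval
PVC_SPEC = SyntheticSpec(
    duration_s=120.0, fs=360.0, mean_hr_bpm=60.0, hr_sd_bpm=0.5,
    ectopic_rate=0.12, noise_snr_db=30.0, seed=7,
)

#: noisy, irregular rhythm for the post-processing trade-off
NOISY_SPEC = SyntheticSpec(
    duration_s=120.0, fs=360.0, mean_hr_bpm=75.0, hr_sd_bpm=10.0,
    ectopic_rate=0.15, noise_snr_db=8.0, seed=3,
)


@pytest.fixture(scope="session")
def clean_ecg():
    return generate_ecg(CLEAN_SPEC)


@pytest.fixture(scope="session")
def short_clean_ecg():
    return generate_ecg(
        SyntheticSpec(duration_s=60.0, fs=360.0, mean_hr_bpm=70.0,
                      noise_snr_db=30.0, seed=2)
    )


@pytest.fixture(scope="session")
def pvc_ecg():
    return generate_ecg(PVC_SPEC)


@pytest.fixture(scope="session")
def noisy_ecg():
    return generate_ecg(NOISY_SPEC)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
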