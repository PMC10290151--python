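import numpy as np
import pytest

from ecgssl.io import CANONICAL_LEADS, EcgRecord
from ecgssl.synthetic import SyntheticSpec, desk_spec, generate_record


@pytest.fixture(scope="session")
def spec_100hz() -> SyntheticSpec:
    """Desk-scale generation conditions (100 Hz, 6 s)."""
    return desk_spec(n_records=1, seed=0)


@pytest.fixture(scope="session")
def clean_record(spec_100hz):
    """One clean normal-rhythm record plus its generation truth."""
    return generate_record(spec_100hz, {"NORM"}, seed=7, record_id="clean")


@pytest.fixture(scope="session")
def spec_500hz() -> SyntheticSpec:
    """Full wearable-format conditions (500 Hz, 15 s)."""
    return SyntheticSpec(n_records=1, fs=500.0, duration_s=15.0, seed=0)


@pytest.fixture()
def random_record() -> EcgRecord:
    rng = np.random.default_rng(3)
    return EcgRecord(rng.standard_normal((12, 400)), 100.0, CANONICAL_LEADS,
                     "rand")


def fixed_rate_record(hr_bpm: float, fs: float = 100.0,
                      duration_s: float = 15.0, seed: int = 11):
    """Clean record at a pinned heart rate (for beat-count oracles)."""
    spec = SyntheticSpec(n_records=1, fs=fs, duration_s=duration_s,
                         hr_range=(hr_bpm, hr_bpm), seed=0)
    return generate_record(spec, {"NORM"}, seed=seed)
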