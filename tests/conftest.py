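import numpy as np
import pandas as pd
import pytest

from usvkit.synth import (
    SessionSpec, make_prototype, render_session, snr_to_amplitude,
)

#: Fixture sampling rate: Nyquist 125 kHz covers the 30-90 kHz call band
#: and the Complex-call overtone while keeping renders cheap.
FIXTURE_FS = 250000.0
FIXTURE_NOISE_RMS = 0.01


def prototype_session(call_type, seed, snr_db=30.0, fs=FIXTURE_FS):
    """A short session containing one prototype call of the given type."""
    amp = snr_to_amplitude(snr_db, FIXTURE_NOISE_RMS)
    proto = make_prototype(call_type, seed, amplitude=amp, onset_s=0.1)
    return SessionSpec(
        sample_rate_hz=fs,
        duration_s=proto.offset_s + 0.1,
        calls=[proto],
        background_noise_rms=FIXTURE_NOISE_RMS,
        seed=seed + 1,
    )


@pytest.fixture(scope="session")
def balanced_toy():
    """2 observations per cell; known by-hand ANOVA decomposition."""
    rows = []
    for g, s, vals in [
        ("WT", "M", [2, 4]), ("WT", "F", [6, 8]),
        ("KO", "M", [1, 3]), ("KO", "F", [5, 7]),
    ]:
        for v in vals:
            rows.append({"genotype": g, "sex": s, "y": float(v)})
    return pd.DataFrame(rows)


def random_unbalanced_table(rng, min_n=3, max_n=20):
    """Random 2x2 Gaussian table with unequal cell sizes."""
    rows = []
    for g in ("WT", "KO"):
        for s in ("M", "F"):
            n = int(rng.integers(min_n, max_n))
            mu, sd = rng.uniform(0, 50), rng.uniform(1, 10)
            for v in rng.normal(mu, sd, n):
                rows.append({"genotype": g, "sex": s, "y": float(v)})
    return pd.DataFrame(rows)
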