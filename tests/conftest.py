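import numpy as np
import pytest

from stann.st_features import cohort_windows
from stann.synthetic import (
    BeatTemplateParams,
    SyntheticCohortSpec,
    make_cohort,
    make_record,
)

HISTORY = ["age", "female", "smoker", "hypertension", "diabetes", "prior_mi", "prior_angiography"]

# modest history effects used by cohort fixtures; the risk signal is mostly
# carried by the ST-series irregularity latent
WEAK_HISTORY = (0.015, -0.1, 0.15, 0.1, 0.2, 0.2, 0.1)


@pytest.fixture(scope="session")
def clean_record():
    """Noiseless template record: 60 beats, ST level 0.1 mV, zero slope."""
    params = BeatTemplateParams(st_level=0.1)
    return make_record(params, 60, seed=11)


@pytest.fixture(scope="session")
def noisy_record():
    params = BeatTemplateParams(st_level=0.08, st_jitter_sd=0.01, noise_sd=0.02, baseline_amp=0.15)
    return make_record(params, 300, seed=12)


@pytest.fixture(scope="session")
def small_cohort():
    """1000-patient cohort with a strong irregularity effect (session-cached)."""
    spec = SyntheticCohortSpec(
        n_patients=1000,
        event_rate=0.034,
        history_effects=WEAK_HISTORY,
        st_irregularity_effect=2.0,
        seed=42,
    )
    cohort, series = make_cohort(spec)
    ids, windows, feats, excluded = cohort_windows(series)
    assert list(cohort["patient_id"]) == ids and not excluded
    return {
        "cohort": cohort,
        "windows": windows,
        "features": feats,
        "history": cohort[HISTORY].to_numpy(dtype=float),
        "y": cohort["event"].to_numpy(dtype=int),
        "time_days": cohort["time_days"].to_numpy(dtype=float),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
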