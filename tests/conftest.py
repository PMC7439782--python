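import pytest
from hypothesis import HealthCheck, settings

from eegid import pipeline, synthetic
from eegid.features import ElectrodeMap

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def emap() -> ElectrodeMap:
    return ElectrodeMap.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully-structured cohort: 5 subjects, 15 short trials."""
    spec = synthetic.CohortSpec(n_subjects=5, trial_seconds=10.0, n_sessions=1, seed=7)
    recs = synthetic.simulate_dataset(spec, sessions=(0,))
    return spec, recs


@pytest.fixture(scope="session")
def small_ds(small_cohort):
    """Normalized feature dataset for the small cohort (150 clips)."""
    _, recs = small_cohort
    ds = pipeline.extract_features(recs)
    return pipeline.normalize_dataset(ds, scope="session")
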