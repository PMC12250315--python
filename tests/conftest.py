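import numpy as np
import pytest

from szforecast.eeg_io import Recording, default_montage_8ch
from szforecast.features import FeatureSpec
from szforecast.forecaster import TrainConfig, make_fold_plan, run_nested_cv
from szforecast.pipeline import prepare_cohort
from szforecast.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def montage():
    return default_montage_8ch()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def flat_recording(n_channels=8, duration_s=600.0, fs=40.0, value=0.0,
                   subject_id="flat", labels=None):
    n = int(duration_s * fs)
    if labels is None:
        labels = [f"ch{i}" for i in range(n_channels)]
    return Recording(subject_id, labels, fs, np.full((n_channels, n), value))


def _cohort_and_cv(strength: float, seed: int):
    cfg = SynthConfig(
        n_subjects=12,
        record_duration=3600.0,
        preictal_strength=strength,
        seed=seed,
    )
    subjects = prepare_cohort(generate_cohort(cfg))
    plan = make_fold_plan(
        [s.subject_id for s in subjects],
        {s.subject_id: s.has_seizures for s in subjects},
        k=6,
        seed=seed,
    )
    result = run_nested_cv(subjects, TrainConfig(seed=seed), plan)
    return subjects, plan, result


@pytest.fixture(scope="session")
def planted_cv():
    """Full pipeline on the planted-signal cohort (preictal_strength=2)."""
    return _cohort_and_cv(strength=2.0, seed=7)


@pytest.fixture(scope="session")
def null_cv():
    """Full pipeline on the null cohort (preictal_strength=0)."""
    return _cohort_and_cv(strength=0.0, seed=7)


@pytest.fixture(scope="session")
def small_null_cohort():
    """Small cohort without a planted preictal signature (strength 0)."""
    cfg = SynthConfig(
        n_subjects=8,
        record_duration=1200.0,
        preictal_strength=0.0,
        seizures_min=1,
        seizures_max=2,
        seed=5,
    )
    return prepare_cohort(
        generate_cohort(cfg), feature_spec=FeatureSpec(rqa_downsample=4)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, small featurized cohort for unit tests (short records)."""
    cfg = SynthConfig(
        n_subjects=8,
        record_duration=1200.0,
        preictal_strength=2.0,
        seizures_min=1,
        seizures_max=2,
        seed=3,
    )
    return prepare_cohort(
        generate_cohort(cfg), feature_spec=FeatureSpec(rqa_downsample=4)
    )
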