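import numpy as np
import pytest

from mossense import aggregation, detection, synthetic_data
from mossense.evaluation import CohortTable, SubjectRecord
from mossense.sensor_model import MS_PER_DAY


@pytest.fixture(scope="session")
def noise_free_subject():
    """One 2-week subject with all behavior noise disabled, plus truth."""
    profile = synthetic_data.SimProfile(
        subject_id="NF", severity_trajectory=[13.5], seed=11,
        noise_level=0.0, phq9_noise_sd=0.0)
    return synthetic_data.simulate_subject_with_truth(profile)


@pytest.fixture(scope="session")
def noisy_subject():
    profile = synthetic_data.SimProfile(
        subject_id="NZ", severity_trajectory=[18.0, 16.0], seed=4)
    return synthetic_data.simulate_subject_with_truth(profile)


@pytest.fixture(scope="session")
def cohort20():
    """Strongly separated 20-subject cohort with its dataset, shared by the
    detection tests and the acceptance suite (simulation is the slow part)."""
    config = synthetic_data.SimCohortConfig(
        n_subjects=20, weeks=4, frac_depressed_baseline=0.5, seed=7,
        noise_level=0.3, phq9_noise_sd=0.0, effect_scale=1.0)
    streams = synthetic_data.simulate_cohort(config)
    frame = aggregation.build_dataset(streams)
    data = detection.dataset_from_frame(frame)
    return streams, frame, data


def make_subject_record(subject_id, adherence_days, n_post_baseline, baseline=12,
                        n_sessions=0, scores=None):
    enrollment = 0
    series = [(enrollment, baseline)]
    for k in range(1, n_post_baseline + 1):
        score = scores[k] if scores else baseline
        series.append((enrollment + k * 14 * MS_PER_DAY, score))
    return SubjectRecord(subject_id=subject_id, enrollment=enrollment,
                         last_activity=enrollment + adherence_days * MS_PER_DAY,
                         phq9_series=series, n_sessions=n_sessions)


@pytest.fixture()
def paper_counts_cohort():
    """Fixture cohort encoding the published attrition counts: 126 enrolled,
    64 gone before week 2, 26 gone in weeks 2-4, 28 adhering >= 4 weeks with
    >= 2 post-baseline scores (8 residual long-adherence subjects lack the
    second score)."""
    rows = []
    i = 0
    for _ in range(64):
        rows.append(make_subject_record(f"A{i}", adherence_days=7, n_post_baseline=0))
        i += 1
    for _ in range(26):
        rows.append(make_subject_record(f"B{i}", adherence_days=20, n_post_baseline=1))
        i += 1
    for _ in range(28):
        rows.append(make_subject_record(f"C{i}", adherence_days=30, n_post_baseline=2))
        i += 1
    for _ in range(8):
        rows.append(make_subject_record(f"D{i}", adherence_days=30, n_post_baseline=1))
        i += 1
    assert len(rows) == 126
    return CohortTable(rows)
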