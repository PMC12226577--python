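import numpy as np
import pytest

from doorecg.dataset import corpus_from_records
from doorecg.segment_average import SEGMENT_LENGTH, HFECGSegment
from doorecg.synth_ecg import (
    NoiseModel,
    SessionSpec,
    make_subject_template,
    simulate_cohort,
    simulate_recording,
)

# Experiment corpora use twelve 20 s records per subject so that the
# beat-level leakage-guarded 70/30 split can supply the full training and
# test compositions up to 5-beat sliding averages.
EXPERIMENT_SESSIONS = [SessionSpec(n_records=12)]


@pytest.fixture(scope="session")
def template1():
    return make_subject_template(1)


@pytest.fixture(scope="session")
def template2():
    return make_subject_template(2)


@pytest.fixture(scope="session")
def noiseless_record(template1):
    """20 s at exactly 60 bpm with all noise terms zero."""
    return simulate_recording(
        template1, duration=20.0, mean_hr=60.0, hr_sd=0.0,
        noise=NoiseModel(), electrode="dispo", seed=0,
    )


@pytest.fixture(scope="session")
def door_cohort():
    """10-subject door-electrode cohort under the default noise preset."""
    return simulate_cohort(10, sessions=EXPERIMENT_SESSIONS, seed=7)


@pytest.fixture(scope="session")
def door_corpus(door_cohort):
    return corpus_from_records(door_cohort)


def make_toy_segment(pattern: np.ndarray, subject: str, beat_id: int = 0,
                     record: str = "rec0", n_avg: int = 1) -> HFECGSegment:
    return HFECGSegment(
        samples=np.asarray(pattern, dtype=float),
        subject_id=subject,
        record_id=record,
        n_avg=n_avg,
        source_beat_ids=tuple(range(beat_id, beat_id + n_avg)),
    )


@pytest.fixture()
def two_subject_toy():
    """Noise-free, widely separated constant templates for two subjects."""
    from doorecg.dataset import LabeledDataset

    a = np.zeros(SEGMENT_LENGTH)
    a[10:30] = 1.0
    b = np.zeros(SEGMENT_LENGTH)
    b[120:140] = -1.0
    segs, labels = [], []
    for i in range(20):
        segs.append(make_toy_segment(a, "A", beat_id=i))
        labels.append("A")
        segs.append(make_toy_segment(b, "B", beat_id=i))
        labels.append("B")
    return LabeledDataset(segs, labels, role="train")
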