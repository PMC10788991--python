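import numpy as np
import pytest

from nyhagrade.io_ecg import ECGRecord, Segment, SegmentSet
from nyhagrade.preprocess import filter_segments, segment_record, zscore_set
from nyhagrade.synthetic import SynthConfig, synth_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def short_record(rng):
    """A 60-second labeled synthetic-looking record at 125 Hz."""
    samples = 0.3 + 0.5 * np.sin(2 * np.pi * 1.2 * np.arange(7500) / 125.0)
    return ECGRecord(subject_id="R1", lead="II", fs=125.0, samples=samples, label=2)


def as_segment(samples, fs=125.0, label=None):
    return Segment(samples=np.asarray(samples, dtype=float), fs=fs,
                   subject_id="T", start=0, label=label)


@pytest.fixture
def tiny_cohort():
    """Two short records per class with ground-truth R peaks, light noise."""
    cfg = SynthConfig(record_seconds=60, n_records_per_class=(2, 2, 2, 2), seed=7)
    records, truths, manifest = synth_dataset(cfg)
    return cfg, records, truths, manifest


@pytest.fixture(scope="session")
def study_dataset():
    """The balanced desk-scale study: 200 z-scored 12-s segments per class."""
    cfg = SynthConfig.reduced_study(seed=11)
    records, _, _ = synth_dataset(cfg)
    segments = []
    for rec in records:
        segments.extend(segment_record(rec, 12).segments)
    retained, _ = filter_segments(
        SegmentSet(segments, duration_s=12, fs=cfg.fs)
    )
    X, y = zscore_set(retained)
    groups = np.array([s.subject_id for s in retained.segments])
    return X, y, groups
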