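"""Train/test pools and augmentation dataset assembly.

Per subject, the base (non-averaged) beat segments of each recording are
split 70/30 at the *source-beat* level: a contiguous 30 % window at a
seeded random position of each recording becomes the test side, the rest
the training side.  Averaged segments are then formed *within* each side,
so no test segment ever shares a source beat with a training segment
(leakage guard for overlapping sliding averages).

Training sets follow named compositions mixing non-averaged, twice- and
three-times-averaged segments at 70 per source type per subject
(70/140/210 total), e.g. ``2,3avg-140TD`` = 70 twice-averaged + 70
three-times-averaged segments per subject.  Test sets are drawn at a
single averaging count, 30 per subject by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import apply_filter1, apply_filter2, detect_r_peaks
from .segment_average import AveragingConfig, HFECGSegment, extract_segments, synchronized_average
from .synth_ecg import ECGRecord

__all__ = [
    "TABLE_COMPOSITIONS",
    "DATASET_IDS",
    "TrainingConfig",
    "training_config",
    "LabeledDataset",
    "SegmentPool",
    "corpus_from_records",
    "split_pool",
    "averaged_pool",
    "build_training_set",
    "build_test_set",
]

# Named training-set compositions: dataset id -> ((n_avg, count per subject), ...)
TABLE_COMPOSITIONS: dict[str, tuple[tuple[int, int], ...]] = {
    "3avg-70TD": ((3, 70),),
    "2avg-70TD": ((2, 70),),
    "1avg-70TD": ((1, 70),),
    "1,2avg-140TD": ((1, 70), (2, 70)),
    "1,3avg-140TD": ((1, 70), (3, 70)),
    "2,3avg-140TD": ((2, 70), (3, 70)),
    "1,2,3avg-210TD": ((1, 70), (2, 70), (3, 70)),
}
DATASET_IDS = tuple(TABLE_COMPOSITIONS)


@dataclass(frozen=True)
class TrainingConfig:
    """A named training-set composition plus split/seed parameters."""

    dataset_id: str
    components: tuple[tuple[int, int], ...]
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(c for _, c in self.components)
        # the TD number in the id states the per-subject total
        td = int(self.dataset_id.split("-")[-1].removesuffix("TD"))
        if total != td:
            raise ValueError(
                f"{self.dataset_id}: component counts sum to {total}, id says {td}"
            )

    @property
    def per_subject_total(self) -> int:
        return sum(c for _, c in self.components)


def training_config(dataset_id: str, seed: int = 0, train_fraction: float = 0.7) -> TrainingConfig:
    if dataset_id not in TABLE_COMPOSITIONS:
        raise ValueError(
            f"unknown dataset id {dataset_id!r}; valid ids: {', '.join(DATASET_IDS)}"
        )
    return TrainingConfig(
        dataset_id=dataset_id,
        components=TABLE_COMPOSITIONS[dataset_id],
        train_fraction=train_fraction,
        seed=seed,
    )


@dataclass
class LabeledDataset:
    """Segments with aligned subject labels, for training or testing."""

    segments: list[HFECGSegment]
    labels: list[str]
    role: str = "train"

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.labels):
            raise ValueError("segments and labels must align")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def X(self) -> np.ndarray:
        from .segment_average import SEGMENT_LENGTH

        if not self.segments:
            return np.empty((0, SEGMENT_LENGTH))
        return np.stack([s.samples for s in self.segments])

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels)


# A pool maps subject -> list of runs; a run is a list of consecutive base
# (n_avg=1) segments from one recording that averaging may slide over.
SegmentPool = dict[str, list[list[HFECGSegment]]]


def corpus_from_records(records: list[ECGRecord], use_true_peaks: bool = False) -> SegmentPool:
    """Run the extraction front end over records and pool base segments.

    Each recording becomes one run of consecutive beat segments (Filter-2
    band, R-anchored).  Beat ids are made unique across a subject's
    recordings by offsetting with the run index so leakage checks can
    compare them globally.
    """
    pool: SegmentPool = {}
    for rec in records:
        if use_true_peaks and rec.true_r_peaks is not None:
            peaks = rec.true_r_peaks
        else:
            peaks = detect_r_peaks(apply_filter1(rec), rec.fs)
        hf = apply_filter2(rec)
        segs = extract_segments(
            hf, peaks, subject_id=rec.subject_id, session=rec.session, record_id=rec.record_id
        )
        if segs:
            pool.setdefault(rec.subject_id, []).append(segs)
    return pool


def split_pool(
    pool: SegmentPool, train_fraction: float = 0.7, seed: int = 0
) -> tuple[SegmentPool, SegmentPool]:
    """Split each subject's runs into disjoint train/test sides by source beat.

    Within every run a contiguous ``1 - train_fraction`` window at a
    seeded random position goes to the test side; the pieces before and
    after it stay on the training side (as separate runs, so averages
    never straddle the cut).  Deterministic under ``seed``.
    """
    if not (0 < train_fraction <= 1):
        raise ValueError("train_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    train: SegmentPool = {}
    test: SegmentPool = {}
    for subject in sorted(pool):
        runs = pool[subject]
        if not runs or not any(runs):
            raise ValueError(f"subject {subject!r} has an empty segment pool")
        train[subject] = []
        test[subject] = []
        for run in runs:
            m = len(run)
            n_test = int(round((1 - train_fraction) * m))
            if n_test == 0:
                train[subject].append(list(run))
                continue
            start = int(rng.integers(0, m - n_test + 1))
            head, mid, tail = run[:start], run[start : start + n_test], run[start + n_test :]
            if head:
                train[subject].append(head)
            if tail:
                train[subject].append(tail)
            test[subject].append(mid)
    return train, test


def averaged_pool(
    pool: SegmentPool, n_avg: int, mode: str = "sliding"
) -> dict[str, list[HFECGSegment]]:
    """Form n-averaged segments within every run; flat list per subject."""
    cfg = AveragingConfig(n=n_avg, mode=mode)
    out: dict[str, list[HFECGSegment]] = {}
    for subject, runs in pool.items():
        segs: list[HFECGSegment] = []
        for run in runs:
            if len(run) < cfg.n:  # split fragments shorter than n are routine
                continue
            segs.extend(synchronized_average(run, cfg))
        out[subject] = segs
    return out


def _draw(
    candidates: list[HFECGSegment],
    count: int,
    rng: np.random.Generator,
    subject: str,
    n_avg: int,
) -> list[HFECGSegment]:
    if len(candidates) < count:
        raise ValueError(
            f"subject {subject!r}: need {count} segments at n_avg={n_avg}, "
            f"have {len(candidates)} (short by {count - len(candidates)})"
        )
    pick = rng.choice(len(candidates), size=count, replace=False)
    return [candidates[i] for i in pick]


def build_training_set(cfg: TrainingConfig, train_pool: SegmentPool) -> LabeledDataset:
    """Assemble a training set matching a named composition exactly.

    Per subject and per component (n_avg, count), ``count`` averaged
    segments are drawn at random without replacement from the subject's
    training side; the final order is shuffled.  Deterministic under
    ``cfg.seed``; a shortfall raises with the subject and missing count.
    """
    rng = np.random.default_rng(cfg.seed)
    by_n = {n: averaged_pool(train_pool, n) for n, _ in cfg.components}
    segments: list[HFECGSegment] = []
    for subject in sorted(train_pool):
        for n_avg, count in cfg.components:
            segments.extend(_draw(by_n[n_avg][subject], count, rng, subject, n_avg))
    order = rng.permutation(len(segments))
    segments = [segments[i] for i in order]
    return LabeledDataset(segments, [s.subject_id for s in segments], role="train")


def build_test_set(
    test_pool: SegmentPool, n_avg: int = 3, per_subject: int = 30, seed: int = 0
) -> LabeledDataset:
    """Draw ``per_subject`` n-averaged segments per subject from the test side."""
    rng = np.random.default_rng(seed)
    by_subject = averaged_pool(test_pool, n_avg)
    segments: list[HFECGSegment] = []
    for subject in sorted(test_pool):
        segments.extend(_draw(by_subject[subject], per_subject, rng, subject, n_avg))
    return LabeledDataset(segments, [s.subject_id for s in segments], role="test")
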