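"""Record normalization, beat-to-beat segmentation and fold assembly.

A record is z-scored per channel over its whole duration, then cut at
consecutive S1 onsets (half-open ``[s_i, s_{i+1})`` slices so adjacent
beats share no samples) and each cardiac cycle is linearly resampled on
the time axis to exactly one second (2,000 samples at 2,000 Hz).
Cross-validation folds are assigned at the segment level, stratified by
label; an optional record-grouped mode keeps all beats of a record in
one fold for stricter evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .errors import DegenerateSignalError, EmptyAnnotationError
from .signal_io import SyncRecord

log = logging.getLogger(__name__)

SEGMENT_LEN = 2000
MIN_BEAT_SAMPLES = 200   # 0.1 s — shorter intervals are annotation glitches
MAX_BEAT_SAMPLES = 6000  # 3 s


@dataclass
class BeatSegment:
    """One cardiac cycle: paired fixed-length ECG and PCG waveforms."""

    ecg: np.ndarray
    pcg: np.ndarray
    label: int
    record_id: str
    beat_index: int

    def __post_init__(self):
        self.ecg = np.asarray(self.ecg, dtype=np.float64)
        self.pcg = np.asarray(self.pcg, dtype=np.float64)
        if self.ecg.shape != self.pcg.shape:
            raise ValueError("ECG/PCG segment shapes differ")


@dataclass
class SegmentDataset:
    segments: list[BeatSegment]
    fold_of: np.ndarray | None = None
    class_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.class_counts:
            self.class_counts = {
                c: sum(1 for s in self.segments if s.label == c)
                for c in (0, 1)
            }

    def __len__(self):
        return len(self.segments)

    def arrays(self, length: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Stack segments into (n, 2, L) inputs and (n,) labels.

        Channel 0 is ECG, channel 1 PCG.  ``length`` optionally
        resamples each waveform (used for reduced-width experiments).
        """
        n = len(self.segments)
        L = length or (self.segments[0].ecg.shape[0] if n else SEGMENT_LEN)
        X = np.empty((n, 2, L))
        for i, s in enumerate(self.segments):
            e, p = s.ecg, s.pcg
            if e.shape[0] != L:
                e = resample_to_length(e, L)
                p = resample_to_length(p, L)
            X[i, 0] = e
            X[i, 1] = p
        y = np.array([s.label for s in self.segments], dtype=np.int64)
        return X, y


def zscore_record(record: SyncRecord) -> SyncRecord:
    """Z-score each channel independently over the whole record."""
    if len(record) < 2:
        raise DegenerateSignalError(f"record {record.record_id}: too short")
    out = {}
    for name in ("ecg", "pcg"):
        x = getattr(record, name)
        sd = x.std()
        if sd == 0:
            raise DegenerateSignalError(
                f"record {record.record_id}: zero-variance {name.upper()} channel"
            )
        out[name] = (x - x.mean()) / sd
    return replace(record, ecg=out["ecg"], pcg=out["pcg"])


def resample_to_length(x: np.ndarray, target_len: int = SEGMENT_LEN) -> np.ndarray:
    """Linear interpolation onto ``target_len`` points spanning the support."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if n < 2:
        raise DegenerateSignalError("cannot resample a signal shorter than 2")
    if n == target_len:
        return x.copy()
    old = np.linspace(0.0, 1.0, n)
    new = np.linspace(0.0, 1.0, target_len)
    return np.interp(new, old, x)


def segment_beats(record: SyncRecord, *,
                  min_len: int = MIN_BEAT_SAMPLES,
                  max_len: int = MAX_BEAT_SAMPLES,
                  segment_len: int = SEGMENT_LEN) -> list[BeatSegment]:
    """Cut a record into per-cycle segments at consecutive S1 onsets.

    K onsets yield K-1 segments; intervals outside ``[min_len, max_len]``
    samples are skipped with a log message (annotation glitches), never
    fatal.  ECG and PCG slices always come from identical sample ranges.
    """
    onsets = record.s1_onsets
    if onsets.size < 2:
        raise EmptyAnnotationError(
            f"record {record.record_id}: need >= 2 S1 onsets to segment"
        )
    if record.label is None:
        raise ValueError(f"record {record.record_id}: label unset")
    segments = []
    for i, (a, b) in enumerate(zip(onsets[:-1], onsets[1:])):
        n = int(b - a)
        if n < min_len or n > max_len:
            log.info("record %s: skipping beat %d (%d samples outside "
                     "[%d, %d])", record.record_id, i, n, min_len, max_len)
            continue
        segments.append(BeatSegment(
            ecg=resample_to_length(record.ecg[a:b], segment_len),
            pcg=resample_to_length(record.pcg[a:b], segment_len),
            label=record.label,
            record_id=record.record_id,
            beat_index=i,
        ))
    return segments


def build_dataset(records: list[SyncRecord],
                  exclusions: tuple[str, ...] = (),
                  label_of: dict[str, int] | None = None) -> SegmentDataset:
    """Normalize, segment and aggregate records into one dataset.

    ``exclusions`` drops records by id (mirrors the manual noise
    exclusion applied to the real data; empty by default since the
    excluded ids are configuration, not derivable).  ``label_of``
    supplies labels for records whose ``label`` is unset.
    """
    excluded = set(exclusions)
    segments: list[BeatSegment] = []
    for rec in records:
        if rec.record_id in excluded:
            continue
        if rec.label is None:
            if not label_of or rec.record_id not in label_of:
                raise ValueError(f"no label for record {rec.record_id}")
            rec = replace(rec, label=label_of[rec.record_id])
        segments.extend(segment_beats(zscore_record(rec)))
    return SegmentDataset(segments=segments)


def make_folds(dataset: SegmentDataset, k: int = 5, seed: int = 0,
               stratify: bool = True, group_by_record: bool = False) -> np.ndarray:
    """Assign each segment a fold id in ``{0..k-1}``; deterministic in seed.

    Default is a segment-level stratified split (the evaluation the
    experiments use); ``group_by_record`` switches to a record-grouped
    stratified split for stricter, leakage-free evaluation.
    """
    y = np.array([s.label for s in dataset.segments])
    n = len(y)
    if stratify:
        for c, cnt in dataset.class_counts.items():
            if 0 < cnt < k:
                raise ValueError(
                    f"class {c} has {cnt} segments; need >= {k} for "
                    f"{k}-fold stratification"
                )
    if n < k:
        raise ValueError(f"{n} segments cannot fill {k} folds")
    fold = np.empty(n, dtype=np.int64)
    X_dummy = np.zeros((n, 1))
    if group_by_record:
        groups = np.array([s.record_id for s in dataset.segments])
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        split = splitter.split(X_dummy, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X_dummy, y)
    for f, (_, test_idx) in enumerate(split):
        fold[test_idx] = f
    return fold
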