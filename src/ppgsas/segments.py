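"""Segmentation, data splits and SNR-calibrated noise injection.

Recordings are cut into non-overlapping windows of 1,500 samples (15 s at
100 Hz), the unit the classifier sees.  Splits follow a 6:2:2
train/validation/test ratio, either at segment level (the protocol replicated
here by default, which lets one subject's segments appear in several parts) or
at subject level (leakage-free alternative).  Gaussian white noise is injected
at a calibrated signal-to-noise ratio for the anti-interference experiment.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synth import PPGRecord

__all__ = [
    "Segment",
    "SegmentSet",
    "SplitAssignment",
    "NoiseSpec",
    "segment_record",
    "segment_cohort",
    "make_split",
    "make_kfold",
    "add_gaussian_noise",
    "measure_snr",
    "standardize",
]

SEGMENT_LENGTH = 1500  # samples: 15 s at 100 Hz


@dataclass
class Segment:
    samples: np.ndarray
    label: int  # 0 = healthy / negative, 1 = SAS / positive
    subject_id: str
    offset_samples: int


@dataclass
class SegmentSet:
    """A stack of fixed-length segments with per-segment provenance."""

    samples: np.ndarray          # (n_segments, segment_length)
    labels: np.ndarray           # (n_segments,) in {0, 1}
    subject_ids: np.ndarray      # (n_segments,) str
    offsets: np.ndarray          # (n_segments,) int

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, idx) -> "SegmentSet":
        idx = np.asarray(idx)
        return SegmentSet(self.samples[idx], self.labels[idx],
                          self.subject_ids[idx], self.offsets[idx])

    @property
    def segment_length(self) -> int:
        return self.samples.shape[1]

    @classmethod
    def from_segments(cls, segments: list) -> "SegmentSet":
        return cls(
            samples=np.stack([s.samples for s in segments]),
            labels=np.array([s.label for s in segments], dtype=np.int64),
            subject_ids=np.array([s.subject_id for s in segments]),
            offsets=np.array([s.offset_samples for s in segments], dtype=np.int64),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.samples)
        with open(path.with_suffix(".csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["segment_id", "subject_id", "label", "offset_samples"])
            for i in range(len(self)):
                w.writerow([i, self.subject_ids[i], self.labels[i], self.offsets[i]])

    @classmethod
    def load(cls, path: str | Path) -> "SegmentSet":
        path = Path(path)
        samples = np.load(path.with_suffix(".npy"))
        subject_ids, labels, offsets = [], [], []
        with open(path.with_suffix(".csv"), newline="") as fh:
            for row in csv.DictReader(fh):
                subject_ids.append(row["subject_id"])
                labels.append(int(row["label"]))
                offsets.append(int(row["offset_samples"]))
        return cls(samples, np.array(labels, dtype=np.int64),
                   np.array(subject_ids), np.array(offsets, dtype=np.int64))


def segment_record(record: PPGRecord, segment_length: int = SEGMENT_LENGTH,
                   labeling: str = "subject") -> list:
    """Cut a record into consecutive non-overlapping windows.

    The trailing remainder shorter than ``segment_length`` is discarded.  With
    ``labeling="subject"`` (default) every segment inherits the subject's
    label; with ``labeling="event"`` a segment of a SAS record is positive
    only if it overlaps an apnea event (synthetic ground truth).
    """
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    if labeling not in ("subject", "event"):
        raise ValueError(f"unknown labeling mode {labeling!r}")
    n_windows = len(record.samples) // segment_length
    subject_label = 1 if record.label == "sas" else 0
    fs = record.sampling_rate_hz
    out = []
    for w in range(n_windows):
        off = w * segment_length
        label = subject_label
        if labeling == "event" and subject_label == 1:
            t0, t1 = off / fs, (off + segment_length) / fs
            label = int(any(ev.onset_s < t1 and ev.end_s > t0 for ev in record.events))
        out.append(Segment(record.samples[off:off + segment_length], label,
                           record.subject_id, off))
    return out


def segment_cohort(records: list, segment_length: int = SEGMENT_LENGTH,
                   labeling: str = "subject") -> SegmentSet:
    segs: list = []
    for rec in records:
        segs.extend(segment_record(rec, segment_length, labeling))
    if not segs:
        raise ValueError("no record is long enough to yield a single segment")
    return SegmentSet.from_segments(segs)


@dataclass
class SplitAssignment:
    """Disjoint train/validation/test index sets covering a SegmentSet."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    mode: str
    seed: int

    def parts(self) -> dict:
        return {"train": self.train, "validation": self.validation, "test": self.test}

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["segment_id", "part"])
            for part, idx in self.parts().items():
                for i in idx:
                    w.writerow([i, part])


def _split_sizes(n: int, ratio: tuple = (6, 2, 2)) -> tuple:
    """6:2:2 sizing: train = round(0.6 N); remainder halved, odd one to train."""
    r_train = ratio[0] / sum(ratio)
    n_train = round(r_train * n)
    rem = n - n_train
    if rem % 2:
        n_train += 1
        rem -= 1
    return n_train, rem // 2, rem // 2


def make_split(segments: SegmentSet, ratio: tuple = (6, 2, 2), mode: str = "segment_level",
               seed: int = 0) -> SplitAssignment:
    """Seeded random 6:2:2 partition of a SegmentSet.

    ``segment_level`` shuffles segments and cuts the permutation at the exact
    ratio sizes.  ``subject_level`` shuffles subjects and assigns each
    subject's segments as a block, greedily filling train, then validation,
    then test up to their segment-count targets, so no subject leaks across
    parts.
    """
    n = len(segments)
    if mode == "segment_level":
        if n < 3:
            raise ValueError(f"need at least 3 segments to split, got {n}")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_train, n_val, n_test = _split_sizes(n, ratio)
        return SplitAssignment(np.sort(perm[:n_train]),
                               np.sort(perm[n_train:n_train + n_val]),
                               np.sort(perm[n_train + n_val:]),
                               mode, seed)
    if mode == "subject_level":
        subjects = np.unique(segments.subject_ids)
        if len(subjects) < 3:
            raise ValueError(f"need at least 3 subjects to split, got {len(subjects)}")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(subjects))
        total = sum(ratio)
        targets = (ratio[0] / total * n, (ratio[0] + ratio[1]) / total * n)
        parts: list = [[], [], []]
        filled = 0
        part = 0
        for s in subjects[order]:
            idx = np.flatnonzero(segments.subject_ids == s)
            if part < 2 and filled >= targets[part]:
                part += 1
            parts[part].append(idx)
            filled += len(idx)
        # guarantee every part holds at least one subject (tiny cohorts)
        for tgt in (1, 2):
            if not parts[tgt]:
                donor = max((p for p in (0, 1) if len(parts[p]) > 1),
                            key=lambda p: len(parts[p]))
                parts[tgt].append(parts[donor].pop())
        return SplitAssignment(*(np.sort(np.concatenate(p)) for p in parts),
                               mode=mode, seed=seed)
    raise ValueError(f"unknown split mode {mode!r}")


def make_kfold(pool: np.ndarray, k: int = 5, seed: int = 0) -> list:
    """Seeded k-fold partition of a training+validation index pool.

    Returns ``k`` (train_idx, validation_idx) pairs; fold ``i`` is held out as
    validation in pair ``i``.  The test part of a prior :func:`make_split` must
    be excluded from ``pool`` by the caller.
    """
    pool = np.asarray(pool)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pool)
    folds = np.array_split(perm, k)
    return [
        (np.sort(np.concatenate([folds[j] for j in range(k) if j != i])), np.sort(folds[i]))
        for i in range(k)
    ]


@dataclass(frozen=True)
class NoiseSpec:
    snr_db: float
    seed: int = 0

    def validate(self) -> None:
        if not math.isfinite(self.snr_db):
            raise ValueError(f"snr_db must be finite, got {self.snr_db}")


def add_gaussian_noise(samples: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Add zero-mean white Gaussian noise at the requested SNR.

    Signal power is the variance of the mean-removed samples; the noise
    variance is P_signal / 10^(snr_db / 10).
    """
    spec.validate()
    x = np.asarray(samples, dtype=np.float64)
    p_signal = float(np.mean((x - x.mean()) ** 2))
    if p_signal <= 0:
        raise ValueError("signal power is zero: SNR is undefined for a constant signal")
    sigma = math.sqrt(p_signal / 10 ** (spec.snr_db / 10))
    rng = np.random.default_rng(spec.seed)
    return x + rng.normal(0.0, sigma, size=x.shape)


def measure_snr(clean: np.ndarray, noisy: np.ndarray) -> float:
    """Realized SNR in dB: 10 log10(P_clean / P_residual).

    Returns ``math.inf`` (the distinguished no-noise result) when the residual
    is identically zero.
    """
    clean = np.asarray(clean, dtype=np.float64)
    noisy = np.asarray(noisy, dtype=np.float64)
    if clean.shape != noisy.shape:
        raise ValueError("clean and noisy arrays must have equal shapes")
    p_clean = float(np.mean((clean - clean.mean()) ** 2))
    if p_clean <= 0:
        raise ValueError("clean signal power is zero")
    residual = noisy - clean
    p_res = float(np.mean(residual ** 2))
    if p_res == 0.0:
        return math.inf
    return 10.0 * math.log10(p_clean / p_res)


def standardize(samples: np.ndarray, sd_floor: float = 1e-8) -> np.ndarray:
    """Per-segment standardization (zero mean, unit sd, sd floored)."""
    x = np.asarray(samples, dtype=np.float64)
    mu = x.mean(axis=-1, keepdims=True)
    sd = np.maximum(x.std(axis=-1, keepdims=True), sd_floor)
    return (x - mu) / sd
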