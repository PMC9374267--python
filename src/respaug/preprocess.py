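"""Segmentation of recordings into respiratory cycles, the 6-second
pad/discard rule, and stratified train/test splitting.

Every downstream stage consumes :class:`AudioSegment` objects: fixed-length
6 s waveforms at 22050 Hz (132300 samples), zero-padded at the end when the
annotated cycle was shorter, discarded when it was strictly longer than 6 s.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import AnnotatedRecording, CLASS_LABELS

log = logging.getLogger(__name__)

SEGMENT_SECONDS = 6.0
SEGMENT_SAMPLE_RATE = 22050
SEGMENT_SAMPLES = int(SEGMENT_SECONDS * SEGMENT_SAMPLE_RATE)  # 132300


@dataclass
class AudioSegment:
    """One fixed-length labeled respiratory cycle."""

    waveform: np.ndarray  # exactly SEGMENT_SAMPLES samples
    label: str
    source: tuple[str, int]  # (recording stem, cycle index)
    original_duration_s: float

    def __post_init__(self):
        if len(self.waveform) != SEGMENT_SAMPLES:
            raise ValueError(
                f"segment must have {SEGMENT_SAMPLES} samples, got "
                f"{len(self.waveform)}"
            )


@dataclass
class SplitDataset:
    train: list[AudioSegment]
    test: list[AudioSegment]
    split_fraction: float
    seed: int


def segment_recording(rec: AnnotatedRecording
                      ) -> list[tuple[np.ndarray, str, float]]:
    """Slice one recording into (waveform, label, duration) per annotation."""
    if not rec.cycles:
        warnings.warn(f"{rec.meta.stem}: no annotations; nothing to segment",
                      stacklevel=2)
        return []
    sr = rec.sample_rate
    out = []
    for c in rec.cycles:
        start = int(round(c.start_s * sr))
        end = min(int(round(c.end_s * sr)), len(rec.waveform))
        out.append((rec.waveform[start:end], rec.diagnosis,
                    (end - start) / sr))
    return out


def pad_or_discard(slices, sources=None) -> list[AudioSegment]:
    """Apply the 6-second rule: pad shorter cycles with trailing silence,
    drop cycles strictly longer than 6 s (an exactly-6 s cycle is kept)."""
    if sources is None:
        sources = [("unknown", i) for i in range(len(slices))]
    segments = []
    for (waveform, label, duration), source in zip(slices, sources):
        n = len(waveform)
        if n > SEGMENT_SAMPLES:
            continue
        padded = np.zeros(SEGMENT_SAMPLES)
        padded[:n] = waveform
        segments.append(AudioSegment(padded, label, source, duration))
    return segments


def segment_corpus(recordings: list[AnnotatedRecording],
                   drop_asthma: bool = True) -> list[AudioSegment]:
    """Segment every recording and apply the 6-second rule.

    Asthma recordings are excluded (the classifiers are 7-class; the source
    corpus has a single Asthma patient) with a logged count.
    """
    segments = []
    n_asthma = n_discarded = n_cycles = 0
    for rec in recordings:
        if drop_asthma and rec.diagnosis == "Asthma":
            n_asthma += len(rec.cycles)
            continue
        slices = segment_recording(rec)
        n_cycles += len(slices)
        sources = [(rec.meta.stem, i) for i in range(len(slices))]
        kept = pad_or_discard(slices, sources)
        n_discarded += len(slices) - len(kept)
        segments.extend(kept)
    log.info(
        "segmented %d cycles: kept %d, discarded %d (>6 s), "
        "dropped %d Asthma cycles",
        n_cycles, len(segments), n_discarded, n_asthma,
    )
    return segments


def stratified_split(segments: list[AudioSegment], fraction: float = 0.7,
                     seed: int = 0, by_recording: bool = False
                     ) -> SplitDataset:
    """Per-class shuffled split with floor(n*fraction) train members.

    ``by_recording=True`` splits at the recording level instead, so all
    cycles of one recording land on the same side (guards against cycles of
    a single patient appearing in both sets).
    """
    by_class: dict[str, list[AudioSegment]] = {}
    for seg in segments:
        by_class.setdefault(seg.label, []).append(seg)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in sorted(by_class):
        members = by_class[label]
        if by_recording:
            stems = sorted({s.source[0] for s in members})
            if len(stems) < 2:
                raise ValueError(
                    f"class {label!r} has fewer than 2 recordings"
                )
            order = rng.permutation(len(stems))
            n_train = max(int(np.floor(len(stems) * fraction)), 1)
            train_stems = {stems[i] for i in order[:n_train]}
            for s in members:
                (train if s.source[0] in train_stems else test).append(s)
        else:
            if len(members) < 2:
                raise ValueError(
                    f"class {label!r} has fewer than 2 segments"
                )
            order = rng.permutation(len(members))
            n_train = max(int(np.floor(len(members) * fraction)), 1)
            for rank, i in enumerate(order):
                (train if rank < n_train else test).append(members[i])
    return SplitDataset(train, test, fraction, seed)


def class_counts(segments: list[AudioSegment]) -> dict[str, int]:
    counts = {c: 0 for c in CLASS_LABELS}
    for seg in segments:
        counts[seg.label] = counts.get(seg.label, 0) + 1
    return {c: n for c, n in counts.items() if n}
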