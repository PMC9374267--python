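"""Reading and writing ICBHI-style respiratory-sound datasets.

A dataset directory holds one WAV file and one annotation text file per
recording, plus a patient-diagnosis CSV.  Recording file stems follow the
ICBHI naming convention::

    <patient>_<recording index>_<chest location>_<acquisition mode>_<equipment>

Annotation files are tab/whitespace-separated with one respiratory cycle per
row: start seconds, end seconds, crackle flag (0/1), wheeze flag (0/1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

log = logging.getLogger(__name__)

#: Closed label vocabulary of the patient-diagnosis table.
DIAGNOSIS_LABELS = (
    "COPD", "Healthy", "URTI", "LRTI", "Bronchiectasis",
    "Bronchiolitis", "Pneumonia", "Asthma",
)

#: The seven classes the classifiers predict (Asthma recordings are dropped
#: during preprocessing; the ICBHI corpus contains a single Asthma patient).
CLASS_LABELS = (
    "COPD", "Healthy", "URTI", "LRTI", "Bronchiectasis",
    "Bronchiolitis", "Pneumonia",
)

#: Six minority (non-COPD) classes that receive synthetic augmentation.
MINORITY_LABELS = tuple(c for c in CLASS_LABELS if c != "COPD")

ANALYSIS_SAMPLE_RATE = 22050


class FormatError(ValueError):
    """Raised on malformed ICBHI-format inputs."""


@dataclass(frozen=True)
class RecordingMeta:
    patient_id: str
    recording_index: str
    chest_location: str
    acquisition_mode: str
    equipment: str

    @property
    def stem(self) -> str:
        return "_".join(
            (self.patient_id, self.recording_index, self.chest_location,
             self.acquisition_mode, self.equipment)
        )


@dataclass(frozen=True)
class CycleAnnotation:
    start_s: float
    end_s: float
    crackle: int
    wheeze: int

    def __post_init__(self):
        if self.start_s < 0 or self.end_s <= self.start_s:
            raise FormatError(
                f"cycle must satisfy 0 <= start < end, got "
                f"({self.start_s}, {self.end_s})"
            )
        if self.crackle not in (0, 1) or self.wheeze not in (0, 1):
            raise FormatError(
                f"crackle/wheeze flags must be 0 or 1, got "
                f"({self.crackle}, {self.wheeze})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AnnotatedRecording:
    meta: RecordingMeta
    waveform: np.ndarray
    sample_rate: int
    cycles: list[CycleAnnotation]
    diagnosis: str

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / self.sample_rate


def parse_filename(stem: str) -> RecordingMeta:
    """Split a 5-field underscore-delimited recording stem."""
    parts = stem.split("_")
    if len(parts) != 5 or not all(parts):
        raise FormatError(
            f"recording stem {stem!r} does not have 5 underscore-separated "
            "fields (patient_recording_location_mode_equipment)"
        )
    return RecordingMeta(*parts)


def read_annotation(path) -> list[CycleAnnotation]:
    """Parse a 4-column cycle annotation text file, preserving row order."""
    cycles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 columns, got {len(cols)}"
                )
            try:
                start, end = float(cols[0]), float(cols[1])
                crackle, wheeze = int(cols[2]), int(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            try:
                cycles.append(CycleAnnotation(start, end, crackle, wheeze))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return cycles


def write_annotation(path, cycles: list[CycleAnnotation]) -> None:
    with open(path, "w") as fh:
        for c in cycles:
            fh.write(f"{c.start_s:.6f}\t{c.end_s:.6f}\t{c.crackle}\t{c.wheeze}\n")


def read_diagnosis(path, header: bool = False) -> dict[str, str]:
    """Read the 2-column ``patient_id,diagnosis`` CSV into a dict."""
    df = pd.read_csv(path, header=0 if header else None, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns, got {df.shape[1]}")
    table: dict[str, str] = {}
    for pid, label in df.itertuples(index=False):
        pid, label = str(pid).strip(), str(label).strip()
        if pid in table:
            raise FormatError(f"{path}: duplicate patient_id {pid!r}")
        if label not in DIAGNOSIS_LABELS:
            raise FormatError(
                f"{path}: unknown diagnosis {label!r} for patient {pid!r}; "
                f"expected one of {', '.join(DIAGNOSIS_LABELS)}"
            )
        table[pid] = label
    return table


def write_diagnosis(path, table: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for pid, label in table.items():
            fh.write(f"{pid},{label}\n")


def read_wav(path, target_sr: int | None = None) -> tuple[np.ndarray, int]:
    """Read a WAV file as mono float64 in [-1, 1], optionally resampling.

    Integer PCM is scaled by its type range; stereo is downmixed by channel
    mean.  Resampling uses polyphase filtering.
    """
    try:
        sr, data = wavfile.read(path)
    except Exception as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        offset = 0.0
        if info.min == 0:  # unsigned PCM (e.g. uint8) is offset binary
            offset = (info.max + 1) / 2.0
            scale = offset
        data = (data.astype(np.float64) - offset) / scale
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if target_sr is not None and target_sr != sr:
        frac = Fraction(target_sr, sr)
        data = resample_poly(data, frac.numerator, frac.denominator)
        sr = target_sr
    return np.clip(data, -1.0, 1.0), sr


def write_wav(path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write mono float32 WAV (lossless round trip up to float32 precision)."""
    wavfile.write(path, sample_rate, np.asarray(waveform, dtype=np.float32))


def load_recording(wav_path, ann_path, diagnosis: str,
                   target_sr: int | None = ANALYSIS_SAMPLE_RATE
                   ) -> AnnotatedRecording:
    """Assemble one annotated recording, clamping small annotation overruns.

    Cycles whose end time exceeds the waveform duration by a small margin
    (as in several real ICBHI files) are clamped to the duration with a
    warning; cycles starting at or beyond the duration are rejected.
    """
    meta = parse_filename(Path(wav_path).stem)
    waveform, sr = read_wav(wav_path, target_sr=target_sr)
    duration = len(waveform) / sr
    cycles = []
    for c in read_annotation(ann_path):
        if c.start_s >= duration:
            raise FormatError(
                f"{ann_path}: cycle starting at {c.start_s:.2f}s lies beyond "
                f"the {duration:.2f}s waveform"
            )
        if c.end_s > duration:
            if c.end_s - duration > 1.0 / sr:  # more than one sample over
                warnings.warn(
                    f"{meta.stem}: clamping cycle end {c.end_s:.2f}s to "
                    f"waveform duration {duration:.2f}s",
                    stacklevel=2,
                )
            c = CycleAnnotation(c.start_s, duration, c.crackle, c.wheeze)
        cycles.append(c)
    return AnnotatedRecording(meta, waveform, sr, cycles, diagnosis)


def load_corpus(directory, diagnosis_csv=None,
                target_sr: int | None = ANALYSIS_SAMPLE_RATE
                ) -> list[AnnotatedRecording]:
    """Load every WAV+TXT pair in ``directory`` with its patient diagnosis."""
    directory = Path(directory)
    if diagnosis_csv is None:
        diagnosis_csv = directory / "diagnosis.csv"
    table = read_diagnosis(diagnosis_csv)
    recordings = []
    for wav_path in sorted(directory.glob("*.wav")):
        ann_path = wav_path.with_suffix(".txt")
        if not ann_path.exists():
            raise FormatError(f"missing annotation file for {wav_path.name}")
        meta = parse_filename(wav_path.stem)
        if meta.patient_id not in table:
            raise FormatError(
                f"patient {meta.patient_id!r} absent from diagnosis table"
            )
        recordings.append(
            load_recording(wav_path, ann_path, table[meta.patient_id],
                           target_sr=target_sr)
        )
    return recordings
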