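"""Audio feature extraction: log-mel spectrograms for the generative
models, Griffin-Lim inversion back to audio, MFCC matrices for the
classifiers, and 39-dimensional MFCC summary vectors for PCA.

The mel front end uses a Hann-windowed, center-padded STFT (n_fft 2048,
hop 512) mapped through a 128-band triangular mel filterbank (HTK mel
scale), log-compressed with a floor, and min-max normalized with
*dataset-level* bounds fitted on the generative-model training set only.
A 6 s segment yields 259 STFT frames; the trailing three are trimmed so
the 128 x 256 grid is divisible by 8, which the stride-2 convolutional
encoder/decoder stacks require.

MFCCs use a hop of 1024 so a 6 s segment yields exactly 130 frames and the
classifier input shape is (13, 130).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import fft as sfft
from scipy.fft import dct
from sklearn.decomposition import PCA

from .preprocess import AudioSegment, SEGMENT_SAMPLES

LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class MelSpecParams:
    n_fft: int = 2048
    hop: int = 512
    n_mels: int = 128
    sample_rate: int = 22050
    frames: int = 256
    norm_min: float | None = None  # dataset-level log-power bounds
    norm_max: float | None = None


@dataclass
class MelSpec:
    """Normalized log-mel matrix (n_mels x frames) with entries in [0, 1]."""

    values: np.ndarray
    params: MelSpecParams
    label: str


@dataclass(frozen=True)
class MFCCParams:
    n_mfcc: int = 13
    n_fft: int = 2048
    hop: int = 1024
    n_mels: int = 128
    sample_rate: int = 22050


# -- STFT / ISTFT ------------------------------------------------------------

@lru_cache(maxsize=8)
def _hann(n_fft: int) -> np.ndarray:
    return np.hanning(n_fft)


@lru_cache(maxsize=8)
def _ola_weight(n_fft: int, hop: int, n_frames: int) -> np.ndarray:
    w2 = _hann(n_fft) ** 2
    total = n_fft + hop * (n_frames - 1)
    wsum = np.zeros(total)
    for t in range(n_frames):
        wsum[t * hop:t * hop + n_fft] += w2
    return np.maximum(wsum, 1e-8)


def stft(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    """Center-padded (reflect) Hann STFT; returns (n_fft//2+1, n_frames)."""
    pad = n_fft // 2
    xp = np.pad(x, pad, mode="reflect")
    n_frames = 1 + (len(xp) - n_fft) // hop
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = xp[idx] * _hann(n_fft)
    return sfft.rfft(frames, axis=1).T


def istft(spec: np.ndarray, n_fft: int, hop: int,
          length: int | None = None) -> np.ndarray:
    """Weighted overlap-add inverse of :func:`stft`."""
    n_frames = spec.shape[1]
    frames = sfft.irfft(spec.T, n=n_fft, axis=1) * _hann(n_fft)
    total = n_fft + hop * (n_frames - 1)
    # overlap-add in hop-sized lanes: reshape frames to (n_frames, k, hop)
    # and accumulate each lane with a shifted strided sum
    x = np.zeros(total + n_fft)
    k = -(-n_fft // hop)
    padded = np.zeros((n_frames, k * hop))
    padded[:, :n_fft] = frames
    lanes = padded.reshape(n_frames, k, hop)
    for lane in range(k):
        view = x[lane * hop:lane * hop + n_frames * hop].reshape(-1, hop)
        view += lanes[:, lane, :]
    x = x[:total] / _ola_weight(n_fft, hop, n_frames)
    pad = n_fft // 2
    x = x[pad:total - pad]
    if length is not None:
        if len(x) < length:
            x = np.pad(x, (0, length - len(x)))
        else:
            x = x[:length]
    return x


# -- mel filterbank ----------------------------------------------------------

def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


@lru_cache(maxsize=8)
def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Triangular filters on the HTK mel scale, peak height 1.

    Returns (n_mels, n_fft//2 + 1).
    """
    fft_freqs = np.linspace(0, sample_rate / 2, n_fft // 2 + 1)
    mel_pts = np.linspace(hz_to_mel(0), hz_to_mel(sample_rate / 2), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for m in range(n_mels):
        lo, center, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / max(center - lo, 1e-9)
        down = (hi - fft_freqs) / max(hi - center, 1e-9)
        fb[m] = np.clip(np.minimum(up, down), 0, None)
    return fb


@lru_cache(maxsize=8)
def _mel_pinv(n_mels: int, n_fft: int, sample_rate: int) -> np.ndarray:
    return np.linalg.pinv(mel_filterbank(n_mels, n_fft, sample_rate))


def mel_center_freqs(n_mels: int, sample_rate: int) -> np.ndarray:
    mel_pts = np.linspace(hz_to_mel(0), hz_to_mel(sample_rate / 2), n_mels + 2)
    return mel_to_hz(mel_pts)[1:-1]


# -- mel spectrogram front end ----------------------------------------------

def log_mel_power(waveform: np.ndarray, params: MelSpecParams) -> np.ndarray:
    """Un-normalized log-power mel matrix, trimmed to ``params.frames``."""
    spec = stft(waveform, params.n_fft, params.hop)
    power = np.abs(spec) ** 2
    fb = mel_filterbank(params.n_mels, params.n_fft, params.sample_rate)
    mel = fb @ power
    logmel = np.log(np.maximum(mel, LOG_FLOOR))
    if logmel.shape[1] < params.frames:
        raise ValueError(
            f"segment too short: {logmel.shape[1]} frames < {params.frames}"
        )
    return logmel[:, :params.frames]


def fit_normalization(segments: list[AudioSegment],
                      params: MelSpecParams) -> MelSpecParams:
    """Fit dataset-level min-max bounds on the given (training) segments."""
    vmin, vmax = np.inf, -np.inf
    for seg in segments:
        lm = log_mel_power(seg.waveform, params)
        vmin = min(vmin, float(lm.min()))
        vmax = max(vmax, float(lm.max()))
    if not np.isfinite(vmin) or vmax <= vmin:
        raise ValueError("degenerate dataset: zero log-mel dynamic range")
    return replace(params, norm_min=vmin, norm_max=vmax)


def mel_spectrogram(segment: AudioSegment, params: MelSpecParams) -> MelSpec:
    """Normalized log-mel spectrogram of one 6 s segment."""
    if len(segment.waveform) != SEGMENT_SAMPLES:
        raise ValueError("mel_spectrogram expects a 6 s AudioSegment")
    if params.norm_min is None or params.norm_max is None:
        raise ValueError(
            "normalization bounds unset; call fit_normalization first"
        )
    lm = log_mel_power(segment.waveform, params)
    values = (lm - params.norm_min) / (params.norm_max - params.norm_min)
    return MelSpec(np.clip(values, 0.0, 1.0), params, segment.label)


def invert_mel(spec: MelSpec, n_iter: int = 32,
               seed: int = 0) -> np.ndarray:
    """Invert a normalized mel spectrogram to audio via Griffin-Lim.

    De-normalize, undo the log, map mel power back to the linear-frequency
    grid with the filterbank pseudo-inverse, then run ``n_iter`` Griffin-Lim
    phase-estimation iterations.
    """
    p = spec.params
    logmel = spec.values * (p.norm_max - p.norm_min) + p.norm_min
    mel_power = np.exp(logmel)
    power = np.clip(
        _mel_pinv(p.n_mels, p.n_fft, p.sample_rate) @ mel_power, 0.0, None
    )
    magnitude = np.sqrt(power)
    rng = np.random.default_rng(seed)
    angles = np.exp(2j * np.pi * rng.random(magnitude.shape))
    x = istft(magnitude * angles, p.n_fft, p.hop)
    for _ in range(n_iter):
        rebuilt = stft(x, p.n_fft, p.hop)[:, :magnitude.shape[1]]
        phase = rebuilt / np.maximum(np.abs(rebuilt), 1e-12)
        x = istft(magnitude * phase, p.n_fft, p.hop)
    if len(x) < SEGMENT_SAMPLES:
        x = np.pad(x, (0, SEGMENT_SAMPLES - len(x)))
    else:
        x = x[:SEGMENT_SAMPLES]
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x = x / peak
    return x


# -- MFCC --------------------------------------------------------------------

def mfcc(segment_or_waveform, params: MFCCParams = MFCCParams()) -> np.ndarray:
    """13 x 130 MFCC matrix: orthonormal DCT-II of log-mel energies."""
    waveform = (
        segment_or_waveform.waveform
        if isinstance(segment_or_waveform, AudioSegment)
        else np.asarray(segment_or_waveform)
    )
    spec = stft(waveform, params.n_fft, params.hop)
    power = np.abs(spec) ** 2
    fb = mel_filterbank(params.n_mels, params.n_fft, params.sample_rate)
    logmel = np.log(np.maximum(fb @ power, LOG_FLOOR))
    coeffs = dct(logmel, type=2, axis=0, norm="ortho")
    return coeffs[:params.n_mfcc]


def summary39(mfcc_matrix: np.ndarray) -> np.ndarray:
    """39-d summary: per-coefficient mean, std and mean first difference."""
    m = np.asarray(mfcc_matrix)
    means = m.mean(axis=1)
    stds = m.std(axis=1)
    deltas = np.diff(m, axis=1).mean(axis=1) if m.shape[1] > 1 else np.zeros(m.shape[0])
    return np.concatenate([means, stds, deltas])


def pca_project(features: np.ndarray, n_components: int = 2
                ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA; returns (coordinates, explained variances)."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 3:
        raise ValueError("PCA needs at least 3 feature vectors")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(features)
    return coords, pca.explained_variance_
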