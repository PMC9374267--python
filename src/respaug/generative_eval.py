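"""Quality metrics for synthetic audio: Fréchet Audio Distance over
pluggable embeddings, a max-normalized-cross-correlation sampling protocol,
and DTW-aligned Mel Cepstral Distortion.

The default embedder is self-contained (per-mel-band log-energy mean and
std over 0.96 s windows) so everything runs offline and deterministically;
an embedder trained on external audio (e.g. VGGish) can be registered
behind the same interface, which changes the FAD scale but not the
machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import MFCCParams, mel_filterbank, mfcc, stft
from .preprocess import AudioSegment

MCD_CONST = 10.0 * np.sqrt(2.0) / np.log(10.0)  # per unit cepstral distance


# -- embeddings --------------------------------------------------------------

def _logmel_stats_embedder(waveform: np.ndarray, sample_rate: int = 22050,
                           n_mels: int = 64, window_s: float = 0.96
                           ) -> np.ndarray:
    """Mean and std of per-band log-mel energies over 0.96 s windows."""
    n_fft, hop = 1024, 512
    spec = np.abs(stft(np.asarray(waveform), n_fft, hop)) ** 2
    fb = mel_filterbank(n_mels, n_fft, sample_rate)
    logmel = np.log(np.maximum(fb @ spec, 1e-10))  # (n_mels, frames)
    frames_per_win = max(int(round(window_s * sample_rate / hop)), 1)
    n_win = logmel.shape[1] // frames_per_win
    if n_win < 1:
        raise ValueError("waveform shorter than one embedding window (~1 s)")
    blocks = logmel[:, :n_win * frames_per_win].reshape(
        n_mels, n_win, frames_per_win
    ).mean(axis=2)  # (n_mels, n_win)
    return np.concatenate([blocks.mean(axis=1), blocks.std(axis=1)])


EMBEDDERS = {"logmel-stats": _logmel_stats_embedder}


def register_embedder(name: str, fn) -> None:
    EMBEDDERS[name] = fn


def embed_audio(waveform: np.ndarray, embedder: str = "logmel-stats"
                ) -> np.ndarray:
    try:
        fn = EMBEDDERS[embedder]
    except KeyError:
        raise ValueError(
            f"unknown embedder {embedder!r}; registered: "
            f"{sorted(EMBEDDERS)}"
        ) from None
    return fn(np.asarray(waveform))


@dataclass
class EmbeddingStats:
    mu: np.ndarray
    sigma: np.ndarray
    n: int

    @classmethod
    def from_embeddings(cls, embeddings: np.ndarray) -> "EmbeddingStats":
        e = np.atleast_2d(np.asarray(embeddings, dtype=float))
        if e.shape[0] < 2:
            raise ValueError("need at least 2 embeddings to fit statistics")
        return cls(e.mean(axis=0), np.cov(e, rowvar=False, ddof=1), e.shape[0])


def frechet_distance(real: EmbeddingStats, gen: EmbeddingStats) -> float:
    """Fréchet (2-Wasserstein²) distance between two Gaussians:
    ||mu_r - mu_g||² + tr(S_r + S_g - 2 (S_r S_g)^{1/2})."""
    if real.mu.shape != gen.mu.shape:
        raise ValueError("embedding dimension mismatch")
    diff = float(((real.mu - gen.mu) ** 2).sum())
    sr = np.atleast_2d(real.sigma)
    sg = np.atleast_2d(gen.sigma)
    eig = np.linalg.eigvals(sr @ sg)
    eig = np.real(eig)
    eig[(eig < 0) & (eig > -1e-8)] = 0.0
    eig = np.clip(eig, 0.0, None)
    trace_term = float(np.trace(sr) + np.trace(sg) - 2.0 * np.sqrt(eig).sum())
    return max(diff + trace_term, 0.0)


def fad_per_class(real_segments: list[AudioSegment],
                  synthetic_segments: list[AudioSegment],
                  embedder: str = "logmel-stats"
                  ) -> tuple[dict[str, float], float]:
    """Per-class FAD of synthetic vs real audio and its unweighted mean."""
    def group(segments):
        by = {}
        for s in segments:
            by.setdefault(s.label, []).append(s.waveform)
        return by

    real_by, syn_by = group(real_segments), group(synthetic_segments)
    missing = set(syn_by) - set(real_by) | set(real_by) - set(syn_by)
    if missing:
        raise ValueError(f"classes missing on one side: {sorted(missing)}")
    fads = {}
    for label in sorted(real_by):
        stats = [
            EmbeddingStats.from_embeddings(
                np.stack([embed_audio(w, embedder) for w in group_waves])
            )
            for group_waves in (real_by[label], syn_by[label])
        ]
        fads[label] = frechet_distance(*stats)
    return fads, mean_fad(fads)


def mean_fad(per_class: dict[str, float]) -> float:
    """Unweighted mean of per-class FAD values (the per-model average)."""
    return float(np.mean(list(per_class.values())))


# -- cross-correlation -------------------------------------------------------

def ncc(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized (Pearson, lag-0) cross-correlation of equal-length signals."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    if denom == 0:
        warnings.warn("zero-energy signal in ncc; returning 0", stacklevel=2)
        return 0.0
    return float(np.clip((x * y).sum() / denom, -1.0, 1.0))


@dataclass
class CCSummary:
    """mean[s][r] / std[s][r]: statistics of the per-synthetic-sample maximum
    correlation between synthetic class ``s`` and real class ``r``."""

    mean: dict[str, dict[str, float]]
    std: dict[str, dict[str, float]]
    n_per_class: int


def _sample(items, n, rng, side, label):
    if len(items) >= n:
        idx = rng.choice(len(items), size=n, replace=False)
        return [items[i] for i in idx]
    warnings.warn(
        f"{side} class {label!r} has only {len(items)} segments "
        f"(< {n}); using all",
        stacklevel=3,
    )
    return list(items)


def cc_matrix(real_by_class: dict[str, list[np.ndarray]],
              syn_by_class: dict[str, list[np.ndarray]],
              n_per_class: int = 50,
              rng: np.random.Generator | None = None) -> CCSummary:
    """For each sampled synthetic segment, the maximum lag-0 correlation over
    sampled real segments of every class; summarized as mean ± std."""
    if rng is None:
        rng = np.random.default_rng(0)
    for by, side in ((real_by_class, "real"), (syn_by_class, "synthetic")):
        for label, items in by.items():
            if not items:
                raise ValueError(f"{side} class {label!r} is empty")
    real_sampled = {
        lab: _sample(v, n_per_class, rng, "real", lab)
        for lab, v in sorted(real_by_class.items())
    }
    syn_sampled = {
        lab: _sample(v, n_per_class, rng, "synthetic", lab)
        for lab, v in sorted(syn_by_class.items())
    }
    mean, std = {}, {}
    for s_lab, syns in syn_sampled.items():
        mean[s_lab], std[s_lab] = {}, {}
        for r_lab, reals in real_sampled.items():
            maxima = [
                max(ncc(s, r) for r in reals) for s in syns
            ]
            mean[s_lab][r_lab] = float(np.mean(maxima))
            std[s_lab][r_lab] = float(np.std(maxima))
    return CCSummary(mean, std, n_per_class)


# -- mel cepstral distortion -------------------------------------------------

def dtw_path(cost: np.ndarray) -> list[tuple[int, int]]:
    """Full-window DTW with the symmetric step pattern (diag/up/left)."""
    n, m = cost.shape
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = cost[i, j] + best
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            candidates.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            candidates.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(candidates, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()
    return path


def mcd(real_mfcc: np.ndarray, syn_mfcc: np.ndarray,
        include_c0: bool = False) -> float:
    """DTW-aligned Mel Cepstral Distortion (dB-scaled) between two MFCC
    matrices (coefficients x frames).  c0 (frame energy) is excluded by
    default, the common convention."""
    a = np.asarray(real_mfcc, float)
    b = np.asarray(syn_mfcc, float)
    if not include_c0:
        a, b = a[1:], b[1:]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 frames per matrix")
    diff = a.T[:, None, :] - b.T[None, :, :]
    cost = np.sqrt((diff ** 2).sum(axis=2))
    path = dtw_path(cost)
    per_pair = np.array([cost[i, j] for i, j in path])
    return float(MCD_CONST * per_pair.mean())


@dataclass
class MCDSummary:
    mean: dict[str, float]
    std: dict[str, float]
    n_per_class: int


def mcd_summary(real_by_class: dict[str, list[AudioSegment]],
                syn_by_class: dict[str, list[AudioSegment]],
                n_per_class: int = 50,
                rng: np.random.Generator | None = None,
                mfcc_params: MFCCParams = MFCCParams()) -> MCDSummary:
    """Per-class mean ± std of DTW-MCD over sampled (synthetic, real) pairs."""
    if rng is None:
        rng = np.random.default_rng(0)
    mean, std = {}, {}
    for label in sorted(syn_by_class):
        if not syn_by_class[label] or not real_by_class.get(label):
            raise ValueError(f"class {label!r} empty on one side")
        syns = _sample(syn_by_class[label], n_per_class, rng,
                       "synthetic", label)
        reals = _sample(real_by_class[label], n_per_class, rng,
                        "real", label)
        syn_m = [mfcc(s, mfcc_params) for s in syns]
        real_m = [mfcc(r, mfcc_params) for r in reals]
        values = [mcd(rm, sm) for sm in syn_m for rm in real_m]
        mean[label] = float(np.mean(values))
        std[label] = float(np.std(values))
    return MCDSummary(mean, std, n_per_class)
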